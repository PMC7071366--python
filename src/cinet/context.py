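"""Weighted bidirectional context integration.

A target stimulus T at position j is flanked by S1 context stimuli on the
left and S2 on the right (span S = S1 + S2). Each slot i in -S1..S2 gets a
coupling weight alpha_i in [0, 1] and its own noise variance; the slot
content is ``alpha_i * pixels + N(0, sigma_i^2)`` (noise added after
weighting, so attenuating a context letter does not attenuate its noise).
The weighted, noisy slots are depth-stacked into a single H x W x Z(1+S)
cuboid — the classifier input. Slices are ordered by increasing i, i.e.
most-distant left context first, then the target (i = 0), then right
context nearest-first. With S1 = S2 = 0 the cuboid is the bare (weighted,
noisy) target: the context-free special case.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stimuli import AmbiguousGlyph, Glyph, NoisyStimulus, render_glyph

__all__ = ["IntegrationConfig", "IntegratedInput", "integrate", "make_word_inputs"]

StimulusLike = Glyph | AmbiguousGlyph | NoisyStimulus | np.ndarray


@dataclass(frozen=True)
class IntegrationConfig:
    """Span, coupling weights and per-slot noise variances.

    ``weights`` and ``noise_variances`` have length S1 + 1 + S2 and are
    indexed by slot i = -S1..S2; index S1 is the target slot (i = 0).
    """

    s1: int
    s2: int
    weights: tuple[float, ...]
    noise_variances: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("spans must be non-negative")
        n = self.s1 + 1 + self.s2
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "noise_variances",
                           tuple(float(v) for v in self.noise_variances))
        if len(self.weights) != n or len(self.noise_variances) != n:
            raise ValueError(f"weights and noise_variances must have length {n}")
        if any(not 0 <= w <= 1 for w in self.weights):
            raise ValueError("weights must lie in [0, 1]")
        if any(v < 0 for v in self.noise_variances):
            raise ValueError("noise variances must be >= 0")

    @property
    def span(self) -> int:
        return self.s1 + self.s2

    @property
    def symmetric(self) -> bool:
        return self.s1 == self.s2

    @classmethod
    def uniform(cls, s1: int, s2: int, weight: float = 1.0,
                variance: float = 0.0, target_weight: float = 1.0,
                target_variance: float | None = None) -> "IntegrationConfig":
        """Same weight/variance on every context slot; the target slot gets
        weight ``target_weight`` and variance ``target_variance`` (defaults
        to the context variance)."""
        n = s1 + 1 + s2
        w = [weight] * n
        v = [variance] * n
        w[s1] = target_weight
        v[s1] = variance if target_variance is None else target_variance
        return cls(s1, s2, tuple(w), tuple(v))


@dataclass(frozen=True)
class IntegratedInput:
    """The depth-stacked classifier input cuboid with slot provenance."""

    cuboid: np.ndarray = field(repr=False)  # H x W x Z(1+S), float64
    slot_labels: tuple[tuple[int, str], ...]  # (slot index i, role/label)

    @property
    def depth(self) -> int:
        return self.cuboid.shape[2]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("cuboid", data=self.cuboid)
            d.attrs["slot_labels"] = [f"{i}:{lab}" for i, lab in self.slot_labels]

    @classmethod
    def from_hdf5(cls, path) -> "IntegratedInput":
        import h5py

        with h5py.File(path, "r") as f:
            cuboid = f["cuboid"][...]
            labels = tuple((int(s.split(":", 1)[0]), s.split(":", 1)[1])
                           for s in f["cuboid"].attrs["slot_labels"])
        return cls(cuboid=cuboid, slot_labels=labels)


def _pixels(s: StimulusLike) -> np.ndarray:
    px = s if isinstance(s, np.ndarray) else s.pixels
    px = np.asarray(px, dtype=np.float64)
    if px.ndim == 2:
        px = px[:, :, None]
    if px.ndim != 3:
        raise ValueError("stimuli must be H x W or H x W x Z arrays")
    return px


def _label(s: StimulusLike) -> str:
    if isinstance(s, NoisyStimulus):
        return _label(s.source)
    return getattr(s, "label", "array")


def integrate(target: StimulusLike,
              left_context: Sequence[StimulusLike],
              right_context: Sequence[StimulusLike],
              config: IntegrationConfig,
              seed: int | None = None,
              rng: np.random.Generator | None = None) -> IntegratedInput:
    """Weight, perturb and depth-stack target plus context into one cuboid.

    Slot i receives ``weights[i] * pixels + N(0, noise_variances[i])`` with
    fresh independent noise per slot. Pass either ``seed`` or an existing
    ``rng``; with all variances zero neither is required.
    """
    if len(left_context) != config.s1:
        raise ValueError(f"expected {config.s1} left context stimuli, got {len(left_context)}")
    if len(right_context) != config.s2:
        raise ValueError(f"expected {config.s2} right context stimuli, got {len(right_context)}")

    ordered = list(left_context) + [target] + list(right_context)
    arrays = [_pixels(s) for s in ordered]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all stimuli must share the same H, W, Z")

    if rng is None and any(v > 0 for v in config.noise_variances):
        if seed is None:
            raise ValueError("a seed or rng is required when noise variances are non-zero")
        rng = np.random.default_rng(seed)

    slices, labels = [], []
    for idx, (arr, stim) in enumerate(zip(arrays, ordered)):
        i = idx - config.s1
        out = config.weights[idx] * arr
        var = config.noise_variances[idx]
        if var > 0:
            out = out + rng.normal(0.0, np.sqrt(var), size=arr.shape)
        slices.append(out)
        labels.append((i, ("target:" if i == 0 else "context:") + _label(stim)))
    return IntegratedInput(cuboid=np.concatenate(slices, axis=2),
                           slot_labels=tuple(labels))


def make_word_inputs(word: str,
                     center_stimulus: StimulusLike,
                     config: IntegrationConfig,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> IntegratedInput:
    """Build the cuboid for a word with its middle letter replaced.

    ``word`` must have length S1 + 1 + S2; the letters around position S1
    are rendered from the committed fixtures and ``center_stimulus`` is
    substituted for the middle letter.
    """
    if len(word) != config.s1 + 1 + config.s2:
        raise ValueError(
            f"word {word!r} has length {len(word)}, config needs {config.s1 + 1 + config.s2}")
    left = [render_glyph(ch) for ch in word[:config.s1]]
    right = [render_glyph(ch) for ch in word[config.s1 + 1:]]
    return integrate(center_stimulus, left, right, config, seed=seed, rng=rng)
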