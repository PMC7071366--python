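"""The six-set classification protocol.

Three pools of classifiers are trained once per run — a context-free
CINET(0) on isolated letters, a CINET(2) on six 3-letter words and a
CINET(4) on six 5-letter words, each from near-noise-free exemplars
(sigma^2 = 0.001 on target and context letters, unity weights). The test
sets then manipulate the context while sweeping zero-mean Gaussian noise
on the (ambiguous or plain) center letter:

====  ==========  ==============================================
Set   classifier  test context
====  ==========  ==============================================
1     CINET(0)    none (isolated center)
2     CINET(2)    congruent, noise-free, unity weights
3     CINET(4)    congruent, noise-free, unity weights
4A    CINET(4)    attenuated weights (0.7, 0.7, 0.7, 0.7)
4B    CINET(4)    decaying weights (0.4, 0.7, 0.7, 0.4)
5     CINET(4)    noise-free weights, context noise = center noise
6     CINET(2)    flipped (left/right exchanged), noise-free
====  ==========  ==============================================

Scoring: with context, a test counts as correct when the decision equals
the class implied by the surrounding word; without context an ambiguous
center counts when the decision lands on either parent. Every table entry
is a two-stage average — mean over networks x samples per test item, then
mean over items.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .context import IntegrationConfig, integrate, make_word_inputs
from .network import Network, NetworkSpec, TrainConfig, TrainResult, train
from .stimuli import AMBIGUOUS_PAIRS, TARGET_LETTERS, make_ambiguous, render_glyph

__all__ = [
    "NOISE_GRID", "TRAIN_WORDS_3", "TRAIN_WORDS_5", "Profile", "CI_PROFILE",
    "FULL_PROFILE", "ExperimentSpec", "ExperimentResult", "standard_spec",
    "train_pool", "run_set", "run_all", "score_ambiguous_contextfree",
    "score_contextual", "derive_seed",
]

#: center-letter noise variances swept in every experiment
NOISE_GRID: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)

#: 3-letter training words, center letters in class order A,H,O,U,P,R
TRAIN_WORDS_3: tuple[str, ...] = ("BAG", "THE", "MOW", "FUN", "SPY", "IRK")

#: 5-letter training words, center letters cover the same six classes
TRAIN_WORDS_5: tuple[str, ...] = ("BEAST", "ETHYL", "GNOME", "FLUID", "IMPLY", "SCREW")

SET_IDS = ("1", "2", "3", "4A", "4B", "5", "6")


def derive_seed(global_seed: int, *tags) -> int:
    """Stable sub-seed (< 2^31) from a global seed and arbitrary tags."""
    crc = zlib.crc32(repr(tags).encode())
    return int(np.random.SeedSequence([int(global_seed), crc]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class Profile:
    """Replication scale: networks per pool, noisy test samples per item,
    and training exemplars per class."""

    n_networks: int
    n_samples: int
    samples_per_class: int


#: desk-scale profile used by the test-suite and acceptance runs
CI_PROFILE = Profile(n_networks=5, n_samples=50, samples_per_class=30)
#: the full replication protocol (30 networks x 100 samples)
FULL_PROFILE = Profile(n_networks=30, n_samples=100, samples_per_class=100)


def score_ambiguous_contextfree(decided: int, parents: tuple[str, str]) -> int:
    """1 iff the decided class is one of the hybrid's two parents."""
    return int(TARGET_LETTERS[decided] in parents)


def score_contextual(decided: int, implied_class: str) -> int:
    """1 iff the decided class is the parent implied by the context word."""
    return int(TARGET_LETTERS[decided] == implied_class)


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one experiment set (one table row)."""

    set_id: str
    s1: int
    s2: int
    train_words: tuple[str, ...] | None  # None -> isolated letters
    test_center: str  # "ambiguous" | "target"
    context_mode: str  # "none" | "congruent" | "weighted" | "noisy" | "flipped"
    context_weights: tuple[float, ...] | None = None
    noise_grid: tuple[float, ...] = NOISE_GRID
    n_networks: int = 30
    n_samples: int = 100
    seed: int = 0
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.test_center not in ("ambiguous", "target"):
            raise ValueError("test_center must be 'ambiguous' or 'target'")
        if self.context_mode not in ("none", "congruent", "weighted", "noisy", "flipped"):
            raise ValueError(f"unknown context_mode {self.context_mode!r}")
        if any(v < 0 for v in self.noise_grid):
            raise ValueError("noise grid values must be >= 0")
        if self.n_networks < 1 or self.n_samples < 1:
            raise ValueError("n_networks and n_samples must be >= 1")
        if self.train_words is not None:
            if len(self.train_words) != len(TARGET_LETTERS):
                raise ValueError("need one training word per target class")
            for word, letter in zip(self.train_words, TARGET_LETTERS):
                if len(word) != self.s1 + 1 + self.s2:
                    raise ValueError(f"word {word!r} does not match span ({self.s1},{self.s2})")
                if word[self.s1] != letter:
                    raise ValueError(f"word {word!r} must have center letter {letter}")
        elif self.context_mode != "none":
            raise ValueError("context manipulation requires training words")
        if self.context_mode == "weighted":
            if self.context_weights is None or len(self.context_weights) != self.s1 + self.s2:
                raise ValueError("weighted mode needs one weight per context slot")

    @property
    def span(self) -> int:
        return self.s1 + self.s2


@dataclass
class ExperimentResult:
    """Raw scores plus the two-stage averaged table row for one set."""

    set_id: str
    test_center: str
    item_labels: tuple[str, ...]  # "center@word" provenance per item
    noise_grid: tuple[float, ...]
    scores: np.ndarray = field(repr=False)  # (items, sigma2, networks, samples) in {0,1}
    manifest: dict = field(default_factory=dict)

    def per_item(self) -> pd.DataFrame:
        """Mean probability per (item, sigma^2) over networks x samples."""
        means = self.scores.mean(axis=(2, 3))
        return pd.DataFrame(means, index=list(self.item_labels),
                            columns=list(self.noise_grid))

    def row(self) -> np.ndarray:
        """Two-stage average: per-item means averaged across items."""
        return self.per_item().to_numpy().mean(axis=0)

    def table(self) -> dict[float, float]:
        return dict(zip(self.noise_grid, self.row()))

    def se(self) -> np.ndarray:
        """Monte-Carlo standard error of each table entry (binomial,
        pooled over items, networks and samples)."""
        p = self.row()
        n = self.scores.shape[0] * self.scores.shape[2] * self.scores.shape[3]
        return np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)

    def subset(self, n_networks: int | None = None,
               n_samples: int | None = None) -> "ExperimentResult":
        """Restrict to the first networks/samples (for scaling checks)."""
        s = self.scores[:, :, :n_networks or None, :n_samples or None]
        return ExperimentResult(self.set_id, self.test_center, self.item_labels,
                                self.noise_grid, s, dict(self.manifest, subset=True))

    def to_frame(self) -> pd.DataFrame:
        """Tidy (set, center, sigma2, probability, se, n) table."""
        p, se = self.row(), self.se()
        n = self.scores.shape[0] * self.scores.shape[2] * self.scores.shape[3]
        return pd.DataFrame({
            "set": self.set_id, "center": self.test_center,
            "sigma2": list(self.noise_grid), "probability": p, "se": se, "n": n,
        })


# ---------------------------------------------------------------------------
# training pools


def _training_set(s1: int, s2: int, words: tuple[str, ...] | None,
                  samples_per_class: int, variance: float, seed: int):
    """Noisy exemplar cuboids + labels for one network's training run."""
    cfg = IntegrationConfig.uniform(s1, s2, weight=1.0, variance=variance)
    rng = np.random.default_rng(seed)
    inputs, labels = [], []
    for cls, letter in enumerate(TARGET_LETTERS):
        center = render_glyph(letter)
        for _ in range(samples_per_class):
            if words is None:
                item = integrate(center, [], [], cfg, rng=rng)
            else:
                item = make_word_inputs(words[cls], center, cfg, rng=rng)
            inputs.append(item.cuboid)
            labels.append(cls)
    return np.asarray(inputs, dtype=np.float32), np.asarray(labels)


def train_pool(s1: int, s2: int, words: tuple[str, ...] | None,
               n_networks: int, train_config: TrainConfig,
               global_seed: int) -> list[TrainResult]:
    """Train ``n_networks`` independently initialised classifiers."""
    spec = NetworkSpec.cinet(s1 + s2)
    results = []
    for i in range(n_networks):
        data_seed = derive_seed(global_seed, "train-data", s1, s2, words, i)
        net_seed = derive_seed(global_seed, "train-net", s1, s2, words, i)
        x, y = _training_set(s1, s2, words, train_config.samples_per_class,
                             train_config.train_noise_variance, data_seed)
        results.append(train(spec, x, y, replace(train_config, seed=net_seed)))
    return results


# ---------------------------------------------------------------------------
# test items and evaluation


def _test_items(spec: ExperimentSpec):
    """(center stimulus, word or None, implied class, label) per test item."""
    items = []
    if spec.train_words is None:
        if spec.test_center == "ambiguous":
            for p1, p2 in AMBIGUOUS_PAIRS:
                hyb = make_ambiguous(p1, p2)
                items.append((hyb, None, None, hyb.label))
        else:
            for letter in TARGET_LETTERS:
                items.append((render_glyph(letter), None, letter, letter))
        return items
    for word, letter in zip(spec.train_words, TARGET_LETTERS):
        if spec.test_center == "ambiguous":
            pair = next(p for p in AMBIGUOUS_PAIRS if letter in p)
            center = make_ambiguous(*pair)
        else:
            center = render_glyph(letter)
        test_word = word[::-1] if spec.context_mode == "flipped" else word
        label = f"{center.label}@{test_word}"
        items.append((center, test_word, letter, label))
    return items


def _context_base(spec: ExperimentSpec, word: str | None, center) -> np.ndarray:
    """Noise-free weighted cuboid for one item (center slice unperturbed)."""
    weights = [1.0] * (spec.span + 1)
    if spec.context_mode == "weighted":
        w = list(spec.context_weights)
        weights = w[:spec.s1] + [1.0] + w[spec.s1:]
    cfg = IntegrationConfig(spec.s1, spec.s2, tuple(weights),
                            (0.0,) * (spec.span + 1))
    if word is None:
        return integrate(center, [], [], cfg).cuboid
    return make_word_inputs(word, center, cfg).cuboid


def run_set(spec: ExperimentSpec,
            networks: list[TrainResult] | None = None) -> ExperimentResult:
    """Evaluate one experiment set.

    If ``networks`` is omitted a fresh pool is trained from the spec
    (sets that reuse another set's classifiers should pass that pool in).
    Networks whose final training loss exceeds 10x the stop threshold are
    excluded with a warning and recorded in the manifest.
    """
    if networks is None:
        networks = train_pool(spec.s1, spec.s2, spec.train_words,
                              spec.n_networks, spec.train_config, spec.seed)
    usable, excluded = [], []
    for i, tr in enumerate(networks):
        if tr.final_loss > 10 * spec.train_config.loss_threshold:
            excluded.append(i)
        else:
            usable.append(tr)
    if excluded:
        warnings.warn(f"set {spec.set_id}: excluded non-convergent networks {excluded}")
    if not usable:
        raise RuntimeError(f"set {spec.set_id}: no convergent networks")

    items = _test_items(spec)
    n_items, n_grid = len(items), len(spec.noise_grid)
    scores = np.zeros((n_items, n_grid, len(usable), spec.n_samples), dtype=np.uint8)
    center_slot = spec.s1 if spec.train_words is not None else 0

    for it, (center, word, implied, label) in enumerate(items):
        base = _context_base(spec, word, center).astype(np.float32)
        for gi, sigma2 in enumerate(spec.noise_grid):
            for ni, tr in enumerate(usable):
                rng = np.random.default_rng(derive_seed(
                    spec.seed, "eval", spec.set_id, spec.test_center, it, gi, ni))
                batch = np.repeat(base[None], spec.n_samples, axis=0)
                std = np.sqrt(sigma2)
                batch[..., center_slot] += rng.normal(
                    0.0, std, size=batch.shape[:3]).astype(np.float32)
                if spec.context_mode == "noisy":
                    for slot in range(spec.span + 1):
                        if slot != center_slot:
                            batch[..., slot] += rng.normal(
                                0.0, std, size=batch.shape[:3]).astype(np.float32)
                decided = tr.network.forward_batch(batch).argmax(axis=1)
                if implied is None:
                    s = [score_ambiguous_contextfree(d, center.parents) for d in decided]
                else:
                    s = [score_contextual(d, implied) for d in decided]
                scores[it, gi, ni] = s

    manifest = {
        "set_id": spec.set_id,
        "test_center": spec.test_center,
        "seed": spec.seed,
        "n_networks": len(usable),
        "n_samples": spec.n_samples,
        "excluded_networks": excluded,
        "train_epochs": [tr.epochs for tr in networks],
        "train_final_loss": [tr.final_loss for tr in networks],
        "train_accuracy": [tr.train_accuracy for tr in networks],
        "converged": [tr.converged for tr in networks],
    }
    return ExperimentResult(spec.set_id, spec.test_center,
                            tuple(lab for *_, lab in items),
                            spec.noise_grid, scores, manifest)


def standard_spec(set_id: str, test_center: str, *, seed: int = 0,
                  profile: Profile = CI_PROFILE,
                  noise_grid: tuple[float, ...] = NOISE_GRID,
                  train_config: TrainConfig | None = None) -> ExperimentSpec:
    """The published configuration of one experiment set."""
    if train_config is None:
        train_config = TrainConfig(samples_per_class=profile.samples_per_class)
    common = dict(test_center=test_center, noise_grid=noise_grid,
                  n_networks=profile.n_networks, n_samples=profile.n_samples,
                  seed=seed, train_config=train_config)
    table = {
        "1": dict(s1=0, s2=0, train_words=None, context_mode="none"),
        "2": dict(s1=1, s2=1, train_words=TRAIN_WORDS_3, context_mode="congruent"),
        "3": dict(s1=2, s2=2, train_words=TRAIN_WORDS_5, context_mode="congruent"),
        "4A": dict(s1=2, s2=2, train_words=TRAIN_WORDS_5, context_mode="weighted",
                   context_weights=(0.7, 0.7, 0.7, 0.7)),
        "4B": dict(s1=2, s2=2, train_words=TRAIN_WORDS_5, context_mode="weighted",
                   context_weights=(0.4, 0.7, 0.7, 0.4)),
        "5": dict(s1=2, s2=2, train_words=TRAIN_WORDS_5, context_mode="noisy"),
        "6": dict(s1=1, s2=1, train_words=TRAIN_WORDS_3, context_mode="flipped"),
    }
    if set_id not in table:
        raise ValueError(f"unknown set id {set_id!r}; choose from {SET_IDS}")
    return ExperimentSpec(set_id=set_id, **table[set_id], **common)


#: which trained pool each set evaluates with
_POOL_OF_SET = {"1": "cinet0", "2": "cinet2", "3": "cinet4",
                "4A": "cinet4", "4B": "cinet4", "5": "cinet4", "6": "cinet2"}
_POOLS = {"cinet0": (0, 0, None), "cinet2": (1, 1, TRAIN_WORDS_3),
          "cinet4": (2, 2, TRAIN_WORDS_5)}


def run_all(seed: int = 0, *, profile: Profile = CI_PROFILE,
            sets: Iterable[str] = SET_IDS,
            centers: Iterable[str] = ("ambiguous", "target"),
            noise_grid: tuple[float, ...] = NOISE_GRID,
            train_config: TrainConfig | None = None,
            ) -> dict[str, dict[str, ExperimentResult]]:
    """Run the selected experiment sets for both center types.

    Trains each classifier pool once and shares it across the sets that
    reuse it (4A/4B/5 reuse the Set-3 CINET(4); 6 reuses the Set-2
    CINET(2)). Returns ``{center: {set_id: ExperimentResult}}``.
    """
    sets = [str(s).upper() for s in sets]
    for s in sets:
        if s not in _POOL_OF_SET:
            raise ValueError(f"unknown set id {s!r}")
    if train_config is None:
        train_config = TrainConfig(samples_per_class=profile.samples_per_class)

    pools: dict[str, list[TrainResult]] = {}
    for pool_name in sorted({_POOL_OF_SET[s] for s in sets}):
        s1, s2, words = _POOLS[pool_name]
        pools[pool_name] = train_pool(s1, s2, words, profile.n_networks,
                                      train_config, derive_seed(seed, pool_name))

    out: dict[str, dict[str, ExperimentResult]] = {}
    for center in centers:
        out[center] = {}
        for set_id in sets:
            spec = standard_spec(set_id, center, seed=seed, profile=profile,
                                 noise_grid=noise_grid, train_config=train_config)
            out[center][set_id] = run_set(spec, networks=pools[_POOL_OF_SET[set_id]])
    return out


def results_frame(results: Mapping[str, Mapping[str, ExperimentResult]]) -> pd.DataFrame:
    """Concatenate every set/center row into one tidy table."""
    frames = [res.to_frame() for by_set in results.values() for res in by_set.values()]
    return pd.concat(frames, ignore_index=True)
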