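"""Visual stimuli: letter glyphs, ambiguous hybrids, and Gaussian pixel noise.

All stimuli are 32x32 binary bitmaps shipped as a committed text fixture
(``data/glyphs.txt``), so every run sees bit-identical glyphs. The fixture
set contains the full alphabet A-Z (six of which are the target classes
A, H, O, U, P, R) plus three hand-designed ambiguous hybrids [A/H],
[O/U], [P/R], each built to be Hamming-equidistant from its two parent
letters and strictly farther from every other target letter.

Ambiguity at test time is introduced by adding i.i.d. zero-mean Gaussian
noise to every pixel (foreground and background); pixel values are left
unclipped so the noise variance is exactly the nominal one.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache

import numpy as np

__all__ = [
    "Glyph",
    "AmbiguousGlyph",
    "NoisyStimulus",
    "TARGET_LETTERS",
    "AMBIGUOUS_PAIRS",
    "render_glyph",
    "make_ambiguous",
    "add_noise",
    "hamming",
]

#: the six stimulus classes, in class-index order 0..5
TARGET_LETTERS: tuple[str, ...] = ("A", "H", "O", "U", "P", "R")

#: parent pairs of the three shipped hybrids
AMBIGUOUS_PAIRS: tuple[tuple[str, str], ...] = (("A", "H"), ("O", "U"), ("P", "R"))

GRID = 32


class MissingFixtureError(KeyError):
    """Requested letter has no committed bitmap."""


@dataclass(frozen=True)
class Glyph:
    """A noise-free binary letter bitmap.

    Attributes
    ----------
    pixels : (32, 32) uint8 array of {0, 1}
    label : letter character
    role : "target" or "context"
    """

    pixels: np.ndarray = field(repr=False)
    label: str
    role: str

    def __post_init__(self) -> None:
        px = self.pixels
        if px.shape != (GRID, GRID) or not np.isin(px, (0, 1)).all():
            raise ValueError("glyph pixels must be a 32x32 binary array")
        n = int(px.sum())
        if not 0 < n < px.size:
            raise ValueError("glyph must contain both foreground and background")


@dataclass(frozen=True)
class AmbiguousGlyph:
    """A hybrid bitmap admitting two mutually exclusive interpretations."""

    pixels: np.ndarray = field(repr=False)
    parents: tuple[str, str]

    @property
    def label(self) -> str:
        return f"[{self.parents[0]}/{self.parents[1]}]"

    role = "ambiguous"


@dataclass(frozen=True)
class NoisyStimulus:
    """A glyph perturbed by additive zero-mean Gaussian pixel noise."""

    pixels: np.ndarray = field(repr=False)
    source: Glyph | AmbiguousGlyph
    variance: float
    seed: int


def _parse_fixture(text: str) -> dict[str, tuple[np.ndarray, str, tuple[str, str] | None]]:
    out: dict[str, tuple[np.ndarray, str, tuple[str, str] | None]] = {}
    name, meta, rows = None, {}, []

    def flush() -> None:
        if name is None:
            return
        px = np.array([[1 if ch == "#" else 0 for ch in r] for r in rows], dtype=np.uint8)
        parents = None
        if "parents" in meta:
            p1, p2 = meta["parents"].split(",")
            parents = (p1, p2)
        out[name] = (px, meta["role"], parents)

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            head = line[1:].split()
            name = head[0]
            meta = dict(kv.split("=", 1) for kv in head[1:])
            rows = []
        else:
            rows.append(line)
    flush()
    return out


@lru_cache(maxsize=1)
def _fixtures() -> dict[str, tuple[np.ndarray, str, tuple[str, str] | None]]:
    text = resources.files("cinet.data").joinpath("glyphs.txt").read_text()
    return _parse_fixture(text)


def available_letters() -> list[str]:
    """Letters with committed bitmaps (single characters only)."""
    return sorted(k for k in _fixtures() if len(k) == 1)


def render_glyph(letter: str) -> Glyph:
    """Return the committed bitmap for ``letter`` (deterministic).

    Raises
    ------
    MissingFixtureError
        If no bitmap is committed for the letter.
    """
    fx = _fixtures()
    if letter not in fx or len(letter) != 1:
        raise MissingFixtureError(f"no committed glyph for letter {letter!r}")
    px, role, _ = fx[letter]
    return Glyph(pixels=px.copy(), label=letter, role=role)


def make_ambiguous(parent1: str, parent2: str) -> AmbiguousGlyph:
    """Return the hand-designed hybrid for an (unordered) parent pair.

    Only the three shipped pairs (A,H), (O,U), (P,R) have fixtures.
    """
    if parent1 == parent2:
        raise ValueError("degenerate pair: parents must differ")
    for p in (parent1, parent2):
        if p not in TARGET_LETTERS:
            raise ValueError(f"{p!r} is not a target letter")
    fx = _fixtures()
    for key in (f"{parent1}/{parent2}", f"{parent2}/{parent1}"):
        if key in fx:
            px, _, parents = fx[key]
            assert parents is not None
            return AmbiguousGlyph(pixels=px.copy(), parents=parents)
    raise MissingFixtureError(f"no hybrid fixture for pair ({parent1},{parent2})")


def add_noise(stimulus: Glyph | AmbiguousGlyph, variance: float, seed: int) -> NoisyStimulus:
    """Add i.i.d. N(0, variance) noise to every pixel, unclipped.

    With ``variance == 0`` the output equals the source bitmap exactly.
    Reproducible: the same (stimulus, variance, seed) gives identical pixels.
    """
    if variance < 0:
        raise ValueError(f"noise variance must be >= 0, got {variance}")
    base = stimulus.pixels.astype(np.float64)
    if variance == 0:
        noisy = base
    else:
        rng = np.random.default_rng(seed)
        noisy = base + rng.normal(0.0, np.sqrt(variance), size=base.shape)
    return NoisyStimulus(pixels=noisy, source=stimulus, variance=float(variance), seed=seed)


def hamming(a: Glyph | AmbiguousGlyph | np.ndarray, b: Glyph | AmbiguousGlyph | np.ndarray) -> int:
    """Hamming distance between two binary bitmaps."""
    pa = a if isinstance(a, np.ndarray) else a.pixels
    pb = b if isinstance(b, np.ndarray) else b.pixels
    return int(np.sum(pa != pb))
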