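"""TE activity dating: K2P divergence, CpG correction, ages, landscapes.

A TE copy's divergence from its family consensus is measured with the Kimura
two-parameter distance

    D = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

where P and Q are the transition and transversion proportions over comparable
(ungapped, unambiguous) columns. Because methylated CpG sites mutate an order
of magnitude faster than other sites, the raw distance is deflated by the
consensus CpG content:

    D_CpG = D / (1 + 9 * F_CpG),      F_CpG = 2 * (#CG dinucleotides) / length

and converted to years with a per-generation substitution rate r and a
generation time g:  age = (D / r) * g.  Divergence landscapes are histograms
of D (or D_CpG) in fixed-width bins, 0.01 substitutions/site by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DivergenceRecord",
    "RateParams",
    "LandscapeSpec",
    "SaturationError",
    "kimura2p",
    "compute_fcpg",
    "cpg_correct",
    "divergence_to_age",
    "landscape",
    "date_copies",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")
_GAPS = frozenset("-.")


class SaturationError(ValueError):
    """Raised when the K2P logarithm's argument is non-positive."""


@dataclass(frozen=True)
class RateParams:
    """Molecular-clock parameters: r subs/site/generation, g years/generation."""

    r: float = 2.5e-8
    g: float = 5.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.g <= 0:
            raise ValueError("rate and generation time must be positive")


@dataclass(frozen=True)
class LandscapeSpec:
    bin_width: float = 0.01

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass(frozen=True)
class DivergenceRecord:
    copy_id: str
    P: float
    Q: float
    D: float
    F_CpG: float
    D_CpG: float
    age_years: float


def kimura2p(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Transition/transversion proportions and K2P distance of an aligned pair.

    Gap and ambiguous (non-ACGT) columns are excluded from the denominator.
    Raises :class:`SaturationError` when 1-2P-Q <= 0 or 1-2Q <= 0, and
    ValueError when no comparable column exists or lengths differ.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / n, tv / n
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P saturated: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}")
    D = -0.5 * math.log(w1 * math.sqrt(w2))
    return P, Q, D


def compute_fcpg(consensus: str) -> float:
    """CpG-site fraction of a consensus: 2 x (CG dinucleotides) / length.

    Overlap cannot occur (CG dinucleotides are disjoint by construction), so
    each CG contributes exactly its two sites.
    """
    if not consensus:
        raise ValueError("empty consensus")
    seq = consensus.upper()
    return 2 * seq.count("CG") / len(seq)


def cpg_correct(D: float, F_CpG: float) -> float:
    """Deflate a raw distance by CpG content: D / (1 + 9 * F_CpG)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if not 0.0 <= F_CpG <= 1.0:
        raise ValueError("F_CpG must be in [0,1]")
    return D / (1 + 9 * F_CpG)


def divergence_to_age(D: float, params: RateParams = RateParams()) -> float:
    """Convert a divergence to years: (D / r) * g."""
    if D < 0:
        raise ValueError("D must be >= 0")
    return (D / params.r) * params.g


def landscape(
    records: Sequence[DivergenceRecord] | Sequence[float],
    spec: LandscapeSpec = LandscapeSpec(),
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Bin divergences into half-open [k*w, (k+1)*w) bins.

    Returns a DataFrame with ``bin_start`` and ``count``; counts sum to the
    number of records.
    """
    if len(records) == 0:
        raise ValueError("no records")
    if isinstance(records[0], DivergenceRecord):
        values = np.array([r.D_CpG if use_corrected else r.D for r in records])
    else:
        values = np.asarray(records, dtype=float)
    w = spec.bin_width
    idx = np.floor(values / w).astype(int)
    counts = np.bincount(idx)
    return pd.DataFrame(
        {"bin_start": np.arange(len(counts)) * w, "count": counts}
    )


def date_copies(
    copies: dict[str, str] | Sequence[tuple[str, str]],
    consensus: str,
    params: RateParams = RateParams(),
    skip_saturated: bool = True,
) -> list[DivergenceRecord]:
    """K2P-date each copy against the consensus (per-copy CpG correction).

    Copies must be positionally aligned to the consensus (equal length,
    substitution-only, gaps allowed as '-'). Saturated copies are skipped
    (or raise, when ``skip_saturated`` is false).
    """
    items = list(copies.items()) if isinstance(copies, dict) else list(copies)
    f_cpg = compute_fcpg(consensus)
    out = []
    for name, seq in items:
        try:
            P, Q, D = kimura2p(consensus, seq)
        except SaturationError:
            if skip_saturated:
                continue
            raise
        d_cpg = cpg_correct(D, f_cpg)
        out.append(
            DivergenceRecord(name, P, Q, D, f_cpg, d_cpg, divergence_to_age(d_cpg, params))
        )
    return out
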