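"""Repertoire summary statistics.

Diversity is Shannon entropy over clonotype proportions, H = -sum p_i ln p_i
(natural log by default; lower H means clonal restriction).  Cross-sample
overlap is the Morisita-Horn index,

    MH = 2 * sum(x_i * y_i) / [(sum x_i^2 / X^2 + sum y_i^2 / Y^2) * X * Y],

an abundance-weighted similarity in [0, 1] that is invariant to proportional
scaling of either count vector.  All statistics operate on cell counts per
clonotype, not UMIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RepertoireProfile:
    """Clonotype -> cell count map for one stratum (sample x optional cell type)."""

    stratum_id: tuple
    counts: Mapping[str, int]
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        for k, n in self.counts.items():
            if n < 1 or n != int(n):
                raise ValueError(f"clonotype {k!r} has non-positive count {n}")

    @property
    def N(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def proportions(self) -> dict[str, float]:
        n = self.N
        return {k: v / n for k, v in self.counts.items()}

    def subsample(self, depth: int, rng: np.random.Generator) -> "RepertoireProfile":
        """Rarefy to ``depth`` cells without replacement (optional depth normalization)."""
        if depth > self.N:
            raise ValueError(f"cannot subsample {depth} cells from {self.N}")
        keys = list(self.counts)
        cells = np.repeat(np.arange(len(keys)), [self.counts[k] for k in keys])
        pick = rng.choice(cells, size=depth, replace=False)
        sub = np.bincount(pick, minlength=len(keys))
        return RepertoireProfile(
            self.stratum_id,
            {k: int(c) for k, c in zip(keys, sub) if c > 0},
            self.patient_id,
        )


def shannon_diversity(profile: RepertoireProfile, base: float = math.e) -> float:
    """Shannon entropy of the clonotype distribution; 0 for a monoclonal repertoire."""
    if not profile.counts:
        raise ValueError("Shannon entropy undefined on an empty repertoire")
    p = np.array(list(profile.counts.values()), dtype=float)
    p /= p.sum()
    h = float(-(p * np.log(p)).sum())
    if base != math.e:
        h /= math.log(base)
    return max(h, 0.0)


def morisita_horn(profile_x: RepertoireProfile, profile_y: RepertoireProfile) -> float:
    """Morisita-Horn similarity over the union of clonotype keys."""
    if not profile_x.counts or not profile_y.counts:
        raise ValueError("Morisita-Horn undefined on an empty repertoire")
    keys = sorted(set(profile_x.counts) | set(profile_y.counts))
    x = np.array([profile_x.counts.get(k, 0) for k in keys], dtype=float)
    y = np.array([profile_y.counts.get(k, 0) for k in keys], dtype=float)
    X, Y = x.sum(), y.sum()
    num = 2.0 * float((x * y).sum())
    den = ((x * x).sum() / X**2 + (y * y).sum() / Y**2) * X * Y
    mh = num / den
    return float(min(max(mh, 0.0), 1.0))


def unique_clonotypes(profile: RepertoireProfile) -> int:
    """Richness: number of distinct clonotypes observed."""
    return len(profile.counts)


def top_n_proportion(profile: RepertoireProfile, n: int = 10) -> float:
    """Summed proportion of the ``n`` most abundant clonotypes.

    Returns 1.0 when richness < n.  Ties at the boundary are resolved
    lexicographically by clonotype id so the result is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not profile.counts:
        raise ValueError("top-n proportion undefined on an empty repertoire")
    ranked = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = sum(c for _, c in ranked[:n])
    return top / profile.N


def similarity_matrix(profiles: Sequence[RepertoireProfile]) -> pd.DataFrame:
    """Pairwise Morisita-Horn matrix across profiles; symmetric, unit diagonal."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    labels = ["|".join(map(str, p.stratum_id)) for p in profiles]
    m = np.eye(len(profiles))
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            m[i, j] = m[j, i] = morisita_horn(profiles[i], profiles[j])
    return pd.DataFrame(m, index=labels, columns=labels)
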