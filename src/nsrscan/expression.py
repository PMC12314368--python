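"""Pearson correlation of stage expression profiles between homologous gene
pairs, contrasted by genomic region (nSR vs syntenic)."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True, slots=True)
class PairCorrelation:
    gene_a: str
    gene_b: str
    r: float  # nan when undefined (zero variance)
    n_stages: int
    region: str  # {nSR, SR}

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; nan when either profile has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("profiles must have at least 3 stages")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("profiles must be finite")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0.0:
        return math.nan
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def pair_correlations(
    homolog_pairs: Sequence[tuple[str, str]],
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    region_labels: Mapping[tuple[str, str], str],
    log1p: bool = False,
) -> list[PairCorrelation]:
    """Per-pair Pearson r with region tag; pairs missing from either matrix
    are skipped with a warning."""
    a = np.log1p(matrix_a) if log1p else matrix_a
    b = np.log1p(matrix_b) if log1p else matrix_b
    out: list[PairCorrelation] = []
    skipped: list[tuple[str, str]] = []
    for ga, gb in homolog_pairs:
        if ga not in a.index or gb not in b.index:
            skipped.append((ga, gb))
            continue
        x = a.loc[ga].to_numpy(dtype=float)
        y = b.loc[gb].to_numpy(dtype=float)
        region = region_labels.get((ga, gb), region_labels.get((gb, ga), "SR"))
        out.append(PairCorrelation(ga, gb, pearson_r(x, y), x.size, region))
    if skipped:
        warnings.warn(
            f"{len(skipped)} pairs missing from expression matrices "
            f"(first: {skipped[:3]})",
            stacklevel=2,
        )
    return out


def summarize_mean_r(
    correlations: Sequence[PairCorrelation],
) -> dict[str, dict[str, float | int]]:
    """Arithmetic mean r per region over defined values; undefined pairs are
    excluded and counted."""
    by_region: dict[str, list[PairCorrelation]] = {}
    for c in correlations:
        by_region.setdefault(c.region, []).append(c)
    summary: dict[str, dict[str, float | int]] = {}
    for region, items in sorted(by_region.items()):
        defined = [c.r for c in items if c.defined]
        summary[region] = {
            "mean_r": float(np.mean(defined)) if defined else math.nan,
            "n_defined": len(defined),
            "n_undefined": len(items) - len(defined),
        }
    return summary
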