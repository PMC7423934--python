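"""Replicate aggregation, count normalization, and the characteristic-protein
presence filter.

Spectral counts arrive as one column per LC-MS/MS run (typically triplicate
runs per sample).  Runs are aggregated to one integer column per sample
(default: sum, which keeps counts integral for the downstream G-test).
Correlation-based analyses consume a normalized real-valued matrix instead;
the G-test always runs on the raw aggregated integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GroupDesign, LepinetError, SpectralCountMatrix

logger = logging.getLogger("lepinet")

#: scale factor applied before the log2 transform, so that values resemble
#: counts-per-ten-thousand (spectral-count depth is ~1e4 spectra per run)
LOG_SCALE = 1e4


@dataclass
class NormalizedMatrix:
    """Protein x sample real-valued expression matrix.

    ``method`` is one of ``total_count`` (columns sum to 1),
    ``log2_total`` (log2(1 + total-count fraction * 1e4)),
    ``log2_mor`` (as log2_total but scaled by median-of-ratios size factors)
    or ``none``.
    """

    values: pd.DataFrame
    method: str
    source: SpectralCountMatrix | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise LepinetError("non-finite normalized value")
        if (arr < 0).any():
            raise LepinetError("negative normalized value")


def aggregate_replicates(m: SpectralCountMatrix, method: str = "sum") -> SpectralCountMatrix:
    """Collapse replicate run columns to one column per sample.

    ``sum`` adds runs (conserves total counts); ``mean_round`` takes the
    per-sample mean rounded half-up to keep integrality.
    """
    if method not in ("sum", "mean_round"):
        raise LepinetError(f"unknown aggregation method {method!r}")
    if not m.has_replicates:
        raise LepinetError("matrix has no replicate columns to aggregate")
    out = {}
    for sample, cols in m.replicate_map.items():
        block = m.counts[cols]
        if method == "sum":
            out[sample] = block.sum(axis=1)
        else:
            # round-half-up, not banker's rounding
            out[sample] = np.floor(block.mean(axis=1) + 0.5).astype(np.int64)
    return SpectralCountMatrix(pd.DataFrame(out, index=m.counts.index))


def normalize(m: SpectralCountMatrix, method: str = "log2_mor") -> NormalizedMatrix:
    """Normalize an aggregated count matrix for correlation analysis.

    ``total_count`` divides each sample column by its total so columns sum
    to 1; ``log2_total`` additionally rescales to counts-per-1e4 and applies
    log2(1 + x).  ``log2_mor`` (the default for co-expression work) first
    divides the total-count fractions by per-sample median-of-ratios size
    factors — the median, over proteins detected in every sample, of the
    ratio of the sample's fraction to the protein's geometric-mean fraction.
    Spectral counts are compositional (runs have a roughly fixed total
    spectrum budget), so a genuinely up-regulated protein group depresses
    every other protein's share in those samples; the median ratio is robust
    to such a minority of shifted proteins and removes the shared per-sample
    offset that total-count scaling leaves behind.
    """
    if m.has_replicates:
        raise LepinetError("aggregate replicates before normalizing")
    if method not in ("total_count", "log2_total", "log2_mor", "none"):
        raise LepinetError(f"unknown normalization method {method!r}")
    counts = m.counts.astype(float)
    if method == "none":
        return NormalizedMatrix(counts, "none", m)
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise LepinetError(f"all-zero sample columns: {zero}")
    frac = counts / totals
    if method == "total_count":
        return NormalizedMatrix(frac, "total_count", m)
    if method == "log2_mor":
        frac = frac / _median_ratio_size_factors(counts, frac)
    return NormalizedMatrix(np.log2(1.0 + frac * LOG_SCALE), method, m)


def _median_ratio_size_factors(counts: pd.DataFrame, frac: pd.DataFrame) -> pd.Series:
    """Per-sample size factors from the median ratio to the geometric-mean
    reference profile, computed over proteins detected in every sample."""
    pos = (counts > 0).all(axis=1)
    if pos.sum() < 10:
        logger.warning(
            "only %d proteins detected in all samples; size factors set to 1", int(pos.sum())
        )
        return pd.Series(1.0, index=counts.columns)
    logf = np.log(frac[pos])
    ref = logf.mean(axis=1)
    return np.exp(logf.sub(ref, axis=0).median(axis=0))


def characteristic_proteins(
    m: SpectralCountMatrix,
    design: GroupDesign,
    min_samples: int = 4,
    include_zero: bool = False,
) -> dict[str, set[str]]:
    """Per-group sets of proteins detected in at least ``min_samples`` samples.

    A protein is "characteristic" of a subtype when its spectral count is
    positive in at least ``min_samples`` of that subtype's samples (the
    default 4 encodes "more than three samples").  ``include_zero`` switches
    the detection rule to SpC >= 0, which trivially admits every protein; it
    is kept only as a fidelity option and is not the default.
    """
    if m.has_replicates:
        raise LepinetError("aggregate replicates before filtering")
    if min_samples < 1:
        raise LepinetError("min_samples must be >= 1")
    out: dict[str, set[str]] = {}
    for g in design.group_labels:
        samples = design.samples_of(g)
        if len(samples) < min_samples:
            logger.warning(
                "group %r has %d samples < min_samples=%d; characteristic set empty",
                g, len(samples), min_samples,
            )
            out[g] = set()
            continue
        block = m.counts[samples]
        detected = (block >= 0) if include_zero else (block > 0)
        hits = detected.sum(axis=1) >= min_samples
        out[g] = set(m.counts.index[hits])
    return out


def presence_overlap_table(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-style overlap counts for per-group protein sets.

    One row per non-empty group combination, with the count of proteins
    exactly in that combination (and in no other group).
    """
    from itertools import combinations

    labels = list(sets)
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[g] for g in combo)) if combo else set()
            outside = set.union(*(sets[g] for g in labels if g not in combo), set())
            exact = inside - outside
            rows.append({"groups": "+".join(combo), "n_proteins": len(exact)})
    return pd.DataFrame(rows)
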