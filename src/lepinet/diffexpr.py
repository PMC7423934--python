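"""Pairwise G-statistics on spectral-count contingency tables.

For every protein and every pair of subtypes a 2x2 table is formed from the
protein's summed spectral counts in each group versus the remaining counts
of that group (the canonical construction for spectral-count G-tests).  The
likelihood-ratio G statistic is divided by Williams' continuity-correction
factor

    q = 1 + (N/R1 + N/R2 - 1)(N/C1 + N/C2 - 1) / (6N)

before referral to a chi-square distribution with 1 df; the correction tames
the small-count inflation of G, which matters here because spectral counts
of rare proteins are small and frequently zero.  Tables with a zero row or
column margin carry no evidence and short-circuit to G = 0, p = 1.

A protein is called *significant to group g* when (a) it is detected in at
least ``presence_min`` of g's samples, (b) its relative abundance share in g
exceeds ``share_min``, and (c) its BH-adjusted q-value is below ``alpha`` in
both pairwise comparisons of g against every other group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import GroupDesign, LepinetError, SpectralCountMatrix
from .preprocess import NormalizedMatrix


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 spectral-count table: rows = protein / rest, columns = groups."""

    f11: float
    f12: float
    f21: float
    f22: float

    def __post_init__(self) -> None:
        if min(self.f11, self.f12, self.f21, self.f22) < 0:
            raise LepinetError("negative cell in contingency table")
        if self.total <= 0:
            raise LepinetError("contingency table has zero total")

    @property
    def row_sums(self) -> tuple[float, float]:
        return (self.f11 + self.f12, self.f21 + self.f22)

    @property
    def col_sums(self) -> tuple[float, float]:
        return (self.f11 + self.f21, self.f12 + self.f22)

    @property
    def total(self) -> float:
        return self.f11 + self.f12 + self.f21 + self.f22

    def as_array(self) -> np.ndarray:
        return np.array([[self.f11, self.f12], [self.f21, self.f22]], dtype=float)


@dataclass
class DiffResult:
    """Full differential-analysis output.

    ``pairwise``: one row per (protein, group pair) with G, the Williams
    divisor, adjusted G, p and BH q.  ``per_group``: one row per
    (protein, group) with presence fraction, relative-abundance share and the
    final significance flag.
    """

    pairwise: pd.DataFrame
    per_group: pd.DataFrame
    alpha: float
    presence_min: float
    share_min: float

    def significant_to(self, group: str) -> list[str]:
        pg = self.per_group
        hit = pg[(pg["group"] == group) & pg["significant"]]
        return sorted(hit["protein"])


def build_contingency(
    m: SpectralCountMatrix, protein: str, design: GroupDesign, group_a: str, group_b: str
) -> ContingencyTable2x2:
    """Protein counts vs remaining counts, summed within each of two groups."""
    if protein not in m.counts.index:
        raise LepinetError(f"unknown protein {protein!r}")
    a_cols = _group_columns(m, design, group_a)
    b_cols = _group_columns(m, design, group_b)
    f11 = float(m.counts.loc[protein, a_cols].sum())
    f12 = float(m.counts.loc[protein, b_cols].sum())
    ta = float(m.counts[a_cols].to_numpy().sum())
    tb = float(m.counts[b_cols].to_numpy().sum())
    return ContingencyTable2x2(f11, f12, ta - f11, tb - f12)


def _group_columns(m: SpectralCountMatrix, design: GroupDesign, group: str) -> list[str]:
    samples = design.samples_of(group)
    if not samples:
        raise LepinetError(f"group {group!r} is empty")
    if m.has_replicates:
        return [c for s in samples for c in m.replicate_map[s]]
    return samples


def g_statistic(table: ContingencyTable2x2) -> tuple[float, float, float, float]:
    """Return ``(G, q_williams, G_adj, p)`` for one 2x2 table."""
    arr = table.as_array()[None, :, :]
    g, q, g_adj, p = _g_statistic_arrays(
        arr[:, 0, 0], arr[:, 0, 1], arr[:, 1, 0], arr[:, 1, 1]
    )
    return float(g[0]), float(q[0]), float(g_adj[0]), float(p[0])


def _g_statistic_arrays(f11, f12, f21, f22):
    """Vectorized G with Williams correction over parallel cell arrays."""
    f11, f12, f21, f22 = (np.asarray(x, dtype=float) for x in (f11, f12, f21, f22))
    r1, r2 = f11 + f12, f21 + f22
    c1, c2 = f11 + f21, f12 + f22
    n = r1 + r2
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.zeros_like(n)
        for obs, rr, cc in ((f11, r1, c1), (f12, r1, c2), (f21, r2, c1), (f22, r2, c2)):
            e = rr * cc / np.where(n > 0, n, 1.0)
            term = np.where(obs > 0, obs * np.log(np.where(obs > 0, obs, 1.0) / np.where(e > 0, e, 1.0)), 0.0)
            g = g + term
        g = 2.0 * g
        q = 1.0 + (n / np.where(r1 > 0, r1, 1.0) + n / np.where(r2 > 0, r2, 1.0) - 1.0) * (
            n / np.where(c1 > 0, c1, 1.0) + n / np.where(c2 > 0, c2, 1.0) - 1.0
        ) / (6.0 * np.where(n > 0, n, 1.0))
    g = np.where(degenerate, 0.0, np.maximum(g, 0.0))
    q = np.where(degenerate, 1.0, q)
    g_adj = g / q
    p = np.where(g <= 0, 1.0, stats.chi2.sf(g_adj, df=1))
    return g, q, g_adj, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise LepinetError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise LepinetError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def relative_abundance(
    nm: NormalizedMatrix, design: GroupDesign, protein: str | None = None
) -> pd.DataFrame:
    """Per-group share of the across-group mean normalized abundance.

    share(g) = mean expression in g / sum over groups of mean expression;
    shares sum to 1 for any protein expressed somewhere.  All-zero proteins
    get NaN shares and ``defined = False``.
    """
    proteins = [protein] if protein is not None else list(nm.values.index)
    for pid in proteins:
        if pid not in nm.values.index:
            raise LepinetError(f"unknown protein {pid!r}")
    means = pd.DataFrame(
        {g: nm.values.loc[proteins, design.samples_of(g)].mean(axis=1) for g in design.group_labels}
    )
    denom = means.sum(axis=1)
    shares = means.div(denom.where(denom > 0), axis=0)
    shares["defined"] = denom > 0
    return shares


def pairwise_g_tests(
    m: SpectralCountMatrix, design: GroupDesign, bh_family: str = "pooled"
) -> pd.DataFrame:
    """G-test every protein for every unordered group pair.

    ``bh_family`` controls the BH correction family: ``pooled`` adjusts all
    (protein, pair) p-values together; ``per_pair`` adjusts within each pair.
    """
    labels = design.group_labels
    if len(labels) < 2:
        raise LepinetError("pairwise tests need at least 2 groups")
    if bh_family not in ("pooled", "per_pair"):
        raise LepinetError(f"unknown bh_family {bh_family!r}")
    counts = m.counts
    frames = []
    for ga, gb in combinations(labels, 2):
        a_cols = _group_columns(m, design, ga)
        b_cols = _group_columns(m, design, gb)
        f11 = counts[a_cols].sum(axis=1).to_numpy(dtype=float)
        f12 = counts[b_cols].sum(axis=1).to_numpy(dtype=float)
        ta, tb = f11.sum(), f12.sum()
        g, q, g_adj, p = _g_statistic_arrays(f11, f12, ta - f11, tb - f12)
        frames.append(
            pd.DataFrame(
                {
                    "protein": counts.index,
                    "group_a": ga,
                    "group_b": gb,
                    "count_a": f11,
                    "count_b": f12,
                    "G": g,
                    "q_williams": q,
                    "G_adj": g_adj,
                    "p": p,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if bh_family == "pooled":
        out["bh_q"] = bh_adjust(out["p"])
    else:
        out["bh_q"] = np.nan
        for _, idx in out.groupby(["group_a", "group_b"]).groups.items():
            out.loc[idx, "bh_q"] = bh_adjust(out.loc[idx, "p"])
    return out


def significant_proteins(
    m: SpectralCountMatrix,
    nm: NormalizedMatrix,
    design: GroupDesign,
    alpha: float = 0.05,
    presence_min: float = 0.6,
    share_min: float = 0.5,
    bh_family: str = "pooled",
) -> DiffResult:
    """Apply the three-part group-significance rule to every protein."""
    labels = design.group_labels
    if len(labels) < 2:
        raise LepinetError("significance calling needs at least 2 groups")
    pairwise = pairwise_g_tests(m, design, bh_family=bh_family)
    shares = relative_abundance(nm, design)

    agg = m.counts
    if m.has_replicates:
        from .preprocess import aggregate_replicates

        agg = aggregate_replicates(m, "sum").counts

    rows = []
    qmap = {}
    for _, r in pairwise.iterrows():
        qmap[(r["protein"], r["group_a"], r["group_b"])] = r["bh_q"]
        qmap[(r["protein"], r["group_b"], r["group_a"])] = r["bh_q"]
    for g in labels:
        samples = design.samples_of(g)
        presence = (agg[samples] > 0).sum(axis=1) / len(samples)
        others = [o for o in labels if o != g]
        for pid in agg.index:
            q_ok = all(qmap[(pid, g, o)] < alpha for o in others)
            share = shares.loc[pid, g]
            share_ok = bool(shares.loc[pid, "defined"]) and share > share_min
            pres_ok = presence[pid] >= presence_min
            rows.append(
                {
                    "protein": pid,
                    "group": g,
                    "presence_fraction": presence[pid],
                    "share": share,
                    "significant": bool(pres_ok and share_ok and q_ok),
                }
            )
    per_group = pd.DataFrame(rows)
    return DiffResult(pairwise, per_group, alpha, presence_min, share_min)
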