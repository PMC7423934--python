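"""Weighted co-expression network analysis of protein abundance profiles.

The pipeline follows the classical WGCNA sequence: pairwise Pearson
correlation of protein expression profiles -> soft-thresholded adjacency
-> topological overlap matrix (TOM) -> average-linkage clustering of the
TOM dissimilarity (1 - TOM) -> dynamic hybrid tree cut into modules ->
per-module hub summary ("eigen-protein") -> module-trait correlation with
Benjamini-Hochberg correction per trait.

Adjacency modes
---------------
``signed``        ((1 + r)/2)^beta   (default; r = 1 -> 1, r = -1 -> 0)
``unsigned``      |r|^beta
``dissim_literal`` ((1 - r)/2)^beta  (maps r = 1 to 0; kept only as a
                  fidelity option for workflows that power the
                  *dissimilarity* transform — it inverts the sign sense and
                  is almost never what you want)

Module summary
--------------
The default module summary is the intramodular hub: the protein with the
highest within-module connectivity sum.  The familiar first-principal-
component eigengene is available via ``summary='pca'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust
from .io_core import GroupDesign, LepinetError
from .preprocess import NormalizedMatrix

logger = logging.getLogger("lepinet")

ADJACENCY_MODES = ("signed", "unsigned", "dissim_literal")

#: deepSplit -> maximum core scatter, on the normalized dendrogram-height
#: scale; the minimum branch gap is (1 - maxCoreScatter) * 3/4 (reference
#: tree-cut convention).
DEEP_SPLIT_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def pearson_matrix(nm: NormalizedMatrix) -> pd.DataFrame:
    """Protein x protein Pearson correlation of expression profiles."""
    vals = nm.values
    if vals.shape[1] < 3:
        raise LepinetError("correlation needs at least 3 samples")
    flat = _flat_profiles(vals)
    if flat:
        raise LepinetError(f"zero-variance proteins (drop first): {flat[:10]}")
    corr = np.corrcoef(vals.to_numpy())
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=vals.index, columns=vals.index)


def _flat_profiles(vals: pd.DataFrame) -> list[str]:
    """Protein ids with (numerically) constant expression profiles."""
    sd = vals.std(axis=1, ddof=0)
    scale = vals.abs().mean(axis=1) + 1.0
    return sd.index[sd <= 1e-12 * scale].tolist()


def drop_zero_variance(nm: NormalizedMatrix) -> tuple[NormalizedMatrix, list[str]]:
    """Remove flat expression profiles; returns the kept matrix and the list
    of dropped protein ids."""
    dropped = _flat_profiles(nm.values)
    kept = nm.values.drop(index=dropped)
    if kept.shape[0] == 0:
        raise LepinetError("all proteins have zero variance")
    return NormalizedMatrix(kept, nm.method, nm.source), dropped


def adjacency(corr: pd.DataFrame, beta: int = 10, mode: str = "signed") -> pd.DataFrame:
    """Soft-threshold a correlation matrix into an adjacency in [0, 1]."""
    if beta < 1:
        raise LepinetError("beta must be >= 1")
    if mode not in ADJACENCY_MODES:
        raise LepinetError(f"unknown adjacency mode {mode!r}; choose from {ADJACENCY_MODES}")
    r = corr.to_numpy()
    if mode == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    elif mode == "unsigned":
        a = np.abs(r) ** beta
    else:
        a = ((1.0 - r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free-topology fit index of a connectivity vector.

    Bins log10(k), regresses log10 frequency on log10 mean connectivity per
    bin, and returns ``(signed_r2, mean_k)`` where the R-squared is negated
    when the slope is positive (scale-free networks have a *decreasing*
    degree distribution).  Returns ``(nan, mean_k)`` when the fit is
    degenerate (fewer than 3 occupied bins or all-equal connectivities).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    mean_k = float(np.mean(k)) if k.size else float("nan")
    if k.size < 3 or np.allclose(k, k[0]):
        return float("nan"), mean_k
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(np.mean(members)))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return float("nan"), mean_k
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2), mean_k


def soft_threshold_fit(
    nm: NormalizedMatrix,
    powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    mode: str = "signed",
    r2_target: float = 0.8,
) -> pd.DataFrame:
    """Scale-free-topology fit for a grid of candidate soft powers.

    Returns one row per power with the signed fit R-squared and mean
    connectivity, plus a ``recommended`` flag on the smallest power reaching
    ``r2_target`` (or, failing that, the power with the best signed R²).
    """
    if len(powers) < 2:
        raise LepinetError("need at least 2 candidate powers")
    corr = pearson_matrix(nm)
    rows = []
    for beta in powers:
        a = adjacency(corr, beta=beta, mode=mode).to_numpy()
        k = a.sum(axis=1) - 1.0  # connectivity excludes the self term
        r2, mean_k = scale_free_fit(k)
        rows.append({"power": beta, "signed_r2": r2, "mean_connectivity": mean_k})
    table = pd.DataFrame(rows)
    table["recommended"] = False
    ok = table["signed_r2"] >= r2_target
    if ok.any():
        table.loc[ok.idxmax(), "recommended"] = True  # first (smallest) power
    elif table["signed_r2"].notna().any():
        table.loc[table["signed_r2"].idxmax(), "recommended"] = True
    return table


def tom(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a [0,1] adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u distinct from i and j, connectivity k excluding the self
    term, unit diagonal by convention, and 0 where the denominator is 0.
    """
    arr = a.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise LepinetError("adjacency must be symmetric")
    if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
        raise LepinetError("adjacency entries must lie in [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    np.fill_diagonal(arr, 1.0)
    k = arr.sum(axis=0) - 1.0
    shared = arr @ arr - 2.0 * arr  # subtracts the u = i and u = j terms (a_ii = 1)
    numer = shared + arr
    denom = np.minimum.outer(k, k) + 1.0 - arr
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, numer / denom, 0.0)
    t = np.clip(t, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=a.index, columns=a.columns)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def hclust_average(diss: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree of a dissimilarity matrix.

    Returns a SciPy linkage matrix.  SciPy's implementation resolves ties
    deterministically by smallest cluster index, so repeated runs on equal
    input produce identical trees.
    """
    arr = diss.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise LepinetError("dissimilarity contains NaN")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise LepinetError("dissimilarity must be symmetric")
    d = arr.copy()
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def dynamic_tree_cut(
    Z: np.ndarray,
    diss: pd.DataFrame,
    deep_split: int = 4,
    min_module_size: int = 10,
    cut_height: float | None = None,
    pam_stage: bool = True,
) -> pd.Series:
    """Dynamic hybrid tree cut: adaptive branch decomposition into modules.

    Walks the merge tree bottom-up, growing branches; when two branches meet
    both are kept as separate modules only if each looks like a genuine
    cluster — at least ``min_module_size`` members, a core scatter (mean
    joining height of the branch core) below a deep-split-dependent
    threshold, and a gap between the attachment height and the core scatter
    above the matching minimum.  Objects left over (attached above declared
    modules) are assigned to the nearest module by average dissimilarity in
    a final PAM-like stage.  Labels: 1, 2, ... by decreasing module size;
    0 = unassigned.
    """
    if deep_split not in DEEP_SPLIT_CORE_SCATTER:
        raise LepinetError("deep_split must be in {0,1,2,3,4}")
    if min_module_size < 2:
        raise LepinetError("min_module_size must be >= 2")
    ids = list(diss.index)
    n = len(ids)
    if n != Z.shape[0] + 1:
        raise LepinetError("linkage and dissimilarity disagree on size")
    heights = Z[:, 2]
    if n < min_module_size:
        return pd.Series(0, index=ids, name="module", dtype=int)

    # normalized-height thresholds (reference tree-cut convention)
    ref_height = float(np.quantile(heights, 0.05))
    if cut_height is None:
        cut_height = 0.99 * (float(heights.max()) - ref_height) + ref_height
    span = max(cut_height - ref_height, 1e-12)
    max_core_scatter = DEEP_SPLIT_CORE_SCATTER[deep_split]
    min_gap = (1.0 - max_core_scatter) * 3.0 / 4.0
    max_abs_core_scatter = ref_height + max_core_scatter * span
    min_abs_gap = min_gap * span

    class Branch:
        __slots__ = ("leaves", "attach_heights", "closed")

        def __init__(self):
            self.leaves: list[int] = []
            self.attach_heights: list[float] = []
            self.closed = False

    def core_size(size: int) -> int:
        base = min_module_size / 2.0 + 1.0
        if base >= size:
            return size
        return int(base + np.sqrt(size - base))

    def core_scatter(br: Branch) -> float:
        cs = core_size(len(br.leaves))
        return float(np.mean(br.attach_heights[:cs])) if cs else 0.0

    def qualifies(br: Branch, attach_h: float) -> bool:
        if len(br.leaves) < min_module_size:
            return False
        scatter = core_scatter(br)
        return scatter <= max_abs_core_scatter and (attach_h - scatter) >= min_abs_gap

    branches: dict[int, Branch] = {}
    final_modules: list[list[int]] = []
    unassigned: list[int] = []

    def singleton(leaf: int, h: float) -> Branch:
        br = Branch()
        br.leaves.append(leaf)
        br.attach_heights.append(h)
        return br

    for i in range(n - 1):
        left, right, h = int(Z[i, 0]), int(Z[i, 1]), float(heights[i])
        lb = branches.pop(left, None) if left >= n else None
        rb = branches.pop(right, None) if right >= n else None
        if h > cut_height:
            # above the cut: nothing merges any more; finalize both sides
            for node, br in ((left, lb), (right, rb)):
                if br is None:
                    unassigned.append(node)
                elif not br.closed:
                    if qualifies(br, h):
                        final_modules.append(br.leaves)
                    else:
                        unassigned.extend(br.leaves)
            nb = Branch()
            nb.closed = True
            branches[n + i] = nb
            continue
        if lb is None and rb is None:
            nb = singleton(left, h)
            nb.leaves.append(right)
            nb.attach_heights.append(h)
        elif lb is None or rb is None:
            nb = rb if lb is None else lb
            leaf = left if lb is None else right
            if nb.closed:
                unassigned.append(leaf)
            else:
                nb.leaves.append(leaf)
                nb.attach_heights.append(h)
        else:
            qa, qb = qualifies(lb, h), qualifies(rb, h)
            if lb.closed or rb.closed:
                for br, q in ((lb, qa), (rb, qb)):
                    if br.closed:
                        continue
                    if q:
                        final_modules.append(br.leaves)
                    else:
                        unassigned.extend(br.leaves)
                nb = Branch()
                nb.closed = True
            elif qa and qb:
                # both sides are genuine clusters: declare them and close
                final_modules.append(lb.leaves)
                final_modules.append(rb.leaves)
                nb = Branch()
                nb.closed = True
            else:
                nb = lb
                nb.leaves.extend(rb.leaves)
                nb.attach_heights.extend(rb.attach_heights)
        branches[n + i] = nb

    root = branches.get(2 * n - 2)
    if root is not None and not root.closed:
        scatter = core_scatter(root)
        if len(root.leaves) >= min_module_size and scatter <= max_abs_core_scatter:
            final_modules.append(root.leaves)
        else:
            unassigned.extend(root.leaves)

    labels = np.zeros(n, dtype=int)
    for mi, leaves in enumerate(
        sorted(final_modules, key=lambda ls: (-len(ls), min(ls))), start=1
    ):
        labels[leaves] = mi

    if pam_stage and final_modules and unassigned:
        d = diss.to_numpy(dtype=float)
        module_idx = {mi + 1: np.array(lv) for mi, lv in enumerate(
            sorted(final_modules, key=lambda ls: (-len(ls), min(ls)))
        )}
        for leaf in unassigned:
            avg = {m: float(d[leaf, idx].mean()) for m, idx in module_idx.items()}
            best = min(avg, key=lambda m: (avg[m], m))
            if avg[best] <= cut_height:
                labels[leaf] = best

    # renumber by decreasing final module size (PAM can reorder sizes)
    out = pd.Series(labels, index=ids, name="module")
    sizes = out[out > 0].value_counts()
    remap = {old: new for new, old in enumerate(
        sorted(sizes.index, key=lambda m: (-sizes[m], m)), start=1)}
    return out.map(lambda m: remap.get(m, 0)).astype(int)


# ---------------------------------------------------------------------------
# module summaries and trait correlation
# ---------------------------------------------------------------------------


def eigen_protein(a: pd.DataFrame, labels: pd.Series) -> dict[int, str]:
    """Most intramodularly connected protein of each module.

    kIM_i = sum of adjacency to the other members; ties broken by
    lexicographically smaller protein id.
    """
    out: dict[int, str] = {}
    for module in sorted(set(labels) - {0}):
        members = list(labels.index[labels == module])
        sub = a.loc[members, members].to_numpy()
        kim = sub.sum(axis=1) - 1.0  # remove the self term a_ii = 1
        best = np.max(kim)
        winners = [members[i] for i in range(len(members)) if kim[i] >= best - 1e-12]
        out[module] = min(winners)
    return out


def module_summary_pca(nm: NormalizedMatrix, labels: pd.Series) -> pd.DataFrame:
    """First-principal-component module eigengenes (optional summary mode).

    Rows are samples, columns are modules; each eigengene is sign-oriented
    to correlate positively with the module's mean expression profile.
    """
    vals = nm.values
    out = {}
    for module in sorted(set(labels) - {0}):
        members = labels.index[labels == module]
        x = vals.loc[members].to_numpy(dtype=float)
        x = (x - x.mean(axis=1, keepdims=True))
        sd = x.std(axis=1, keepdims=True)
        x = np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        pc = vt[0]
        mean_profile = x.mean(axis=0)
        if np.dot(pc, mean_profile) < 0:
            pc = -pc
        out[module] = pc
    return pd.DataFrame(out, index=vals.columns)


def module_trait_correlation(
    nm: NormalizedMatrix,
    eigen: dict[int, str],
    design: GroupDesign,
    r_screen: float = 0.5,
    alpha: float = 0.05,
    bh_family: str = "per_trait",
) -> pd.DataFrame:
    """Correlate each module's summary profile with each binary subtype trait.

    p-values come from the exact t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 df (two-sided); BH is applied per trait across modules (``pooled``
    adjusts all module x trait p-values together).  ``high_corr`` flags
    |r| > ``r_screen`` and ``significant`` flags q < ``alpha``.
    """
    samples = nm.values.columns
    if len(samples) < 3:
        raise LepinetError("trait correlation needs at least 3 samples")
    if bh_family not in ("per_trait", "pooled"):
        raise LepinetError(f"unknown bh_family {bh_family!r}")
    traits = design.trait_vectors.loc[samples]
    rows = []
    for module, pid in sorted(eigen.items()):
        profile = nm.values.loc[pid, samples].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            if profile.std() == 0 or tv.std() == 0:
                rows.append({"module": module, "trait": trait, "eigen_protein": pid,
                             "r": np.nan, "p": np.nan})
                continue
            r = float(np.corrcoef(profile, tv)[0, 1])
            n = len(profile)
            r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
            t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            rows.append({"module": module, "trait": trait, "eigen_protein": pid,
                         "r": r, "p": p})
    table = pd.DataFrame(rows)
    table["bh_q"] = np.nan
    defined = table["p"].notna()
    if defined.any():
        if bh_family == "pooled":
            table.loc[defined, "bh_q"] = bh_adjust(table.loc[defined, "p"])
        else:
            for _, idx in table[defined].groupby("trait").groups.items():
                table.loc[idx, "bh_q"] = bh_adjust(table.loc[idx, "p"])
    table["high_corr"] = table["r"].abs() > r_screen
    table["significant"] = table["bh_q"] < alpha
    return table


# ---------------------------------------------------------------------------
# end-to-end model
# ---------------------------------------------------------------------------


@dataclass
class CoexprModel:
    """Fitted co-expression network with module labels and trait statistics."""

    corr: pd.DataFrame
    power: int
    mode: str
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series
    eigen_proteins: dict[int, str]
    trait_stats: pd.DataFrame
    dropped_proteins: list[str] = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return int((self.labels.unique() > 0).sum())


def fit_coexpression(
    nm: NormalizedMatrix,
    design: GroupDesign,
    power: int = 10,
    mode: str = "signed",
    deep_split: int = 4,
    min_module_size: int = 10,
    pam_stage: bool = True,
    r_screen: float = 0.5,
    alpha: float = 0.05,
) -> CoexprModel:
    """Run the full module-discovery pipeline on a normalized matrix.

    Zero-variance proteins are dropped (with a log message) before the
    correlation step; everything downstream is deterministic in the input.
    """
    nm2, dropped = drop_zero_variance(nm)
    if dropped:
        logger.info("dropped %d zero-variance proteins", len(dropped))
    corr = pearson_matrix(nm2)
    a = adjacency(corr, beta=power, mode=mode)
    t = tom(a)
    diss = 1.0 - t
    Z = hclust_average(diss)
    labels = dynamic_tree_cut(
        Z, diss, deep_split=deep_split, min_module_size=min_module_size,
        pam_stage=pam_stage,
    )
    eig = eigen_protein(a, labels)
    trait_stats = module_trait_correlation(
        nm2, eig, design, r_screen=r_screen, alpha=alpha
    )
    return CoexprModel(corr, power, mode, a, t, Z, labels, eig, trait_stats, dropped)
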