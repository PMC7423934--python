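"""Seeded synthetic spectral-count cohorts and PPI networks.

The generator emulates the statistical shape of a small label-free
proteomics cohort: three subtype groups of 5/5/4 samples, ~2,000 proteins,
triplicate LC-MS/MS runs per sample, a fixed expected depth of 1e4 spectra
per run, compositional counts (softmax of per-sample log-abundance times
depth), and count noise that is Poisson or negative-binomial
(gamma-Poisson) with abundant zeros for low-abundance proteins.

Structure is planted on the natural-log abundance scale:

* co-expressed modules: each module shares a latent per-sample factor
  (standard normal, mean-shifted by ``trait_shift`` in the linked subtype's
  samples when the module is trait-linked), entering every member's
  log-abundance scaled by the module ``loading``;
* group-specific differential proteins: an additive log fold-change in the
  target group's samples.

Everything is driven by one mandatory seed, so identical specs yield
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_core import GroupDesign, LepinetError, SpectralCountMatrix

DEFAULT_GROUP_LABELS = ("AIS", "MIA", "LPA")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module; ``link`` names a group or is None."""

    size: int
    link: str | None = None
    loading: float = 0.9


@dataclass(frozen=True)
class DifferentialSpec:
    """``n`` proteins up-shifted ``fold``-fold in ``group``."""

    n: int
    group: str
    fold: float


@dataclass
class SimSpec:
    """Parameters of one synthetic cohort."""

    seed: int
    group_sizes: tuple[int, ...] = (5, 5, 4)
    group_labels: tuple[str, ...] | None = None
    n_proteins: int = 2000
    n_replicates: int = 3
    depth: float = 1e4
    modules: tuple[ModuleSpec, ...] = ()
    differential: tuple[DifferentialSpec, ...] = ()
    noise: str = "poisson"
    dispersion: float = 0.2
    baseline_sd: float = 1.0
    trait_shift: float = 4.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise LepinetError("seed is mandatory")
        if self.group_labels is None:
            if len(self.group_sizes) <= len(DEFAULT_GROUP_LABELS):
                self.group_labels = DEFAULT_GROUP_LABELS[: len(self.group_sizes)]
            else:
                self.group_labels = tuple(f"G{i+1}" for i in range(len(self.group_sizes)))
        if len(self.group_labels) != len(self.group_sizes):
            raise LepinetError("group_labels and group_sizes disagree")
        if any(n < 2 for n in self.group_sizes):
            raise LepinetError("every group needs >= 2 samples")
        if sum(m.size for m in self.modules) > self.n_proteins:
            raise LepinetError("module sizes exceed n_proteins")
        for m in self.modules:
            if m.link is not None and m.link not in self.group_labels:
                raise LepinetError(f"module linked to unknown group {m.link!r}")
        if sum(d.n for d in self.differential) > self.n_proteins:
            raise LepinetError("differential proteins exceed n_proteins")
        for d in self.differential:
            if d.group not in self.group_labels:
                raise LepinetError(f"differential targets unknown group {d.group!r}")
            if d.fold <= 0:
                raise LepinetError("fold-change must be > 0")
        if self.noise not in ("poisson", "negbin"):
            raise LepinetError(f"unknown noise model {self.noise!r}")
        if self.noise == "negbin" and self.dispersion <= 0:
            raise LepinetError("negbin dispersion must be > 0")
        if self.n_replicates < 1 or self.n_proteins < 1 or self.depth <= 0:
            raise LepinetError("infeasible spec")


@dataclass
class Truth:
    """Ground truth of a simulated cohort."""

    module_labels: pd.Series  # protein -> module id (0 = background)
    module_links: dict[int, str | None]
    differential: pd.DataFrame  # columns: protein, group, fold
    expected_counts: pd.DataFrame = field(repr=False, default=None)


def simulate_counts(spec: SimSpec) -> tuple[SpectralCountMatrix, GroupDesign, Truth]:
    """Draw one synthetic cohort from a :class:`SimSpec`."""
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    samples, groups = [], []
    for label, size in zip(spec.group_labels, spec.group_sizes):
        for i in range(size):
            samples.append(f"{label}_{i + 1:02d}")
            groups.append(label)
    design = GroupDesign(pd.Series(groups, index=samples, name="group"))
    n_s = len(samples)

    log_abund = np.tile(
        rng.normal(0.0, spec.baseline_sd, size=spec.n_proteins)[:, None], (1, n_s)
    )

    module_labels = np.zeros(spec.n_proteins, dtype=int)
    module_links: dict[int, str | None] = {}
    cursor = 0
    for mi, mod in enumerate(spec.modules, start=1):
        members = slice(cursor, cursor + mod.size)
        cursor += mod.size
        module_labels[members] = mi
        module_links[mi] = mod.link
        factor = rng.normal(0.0, 1.0, size=n_s)
        if mod.link is not None:
            factor = factor + spec.trait_shift * design.trait_vectors[mod.link].to_numpy()
        log_abund[members, :] += mod.loading * factor[None, :]

    diff_rows = []
    for dspec in spec.differential:
        members = range(cursor, cursor + dspec.n)
        cursor += dspec.n
        mask = (design.groups == dspec.group).to_numpy()
        for p in members:
            log_abund[p, mask] += np.log(dspec.fold)
            diff_rows.append({"protein": proteins[p], "group": dspec.group, "fold": dspec.fold})

    # compositional expected counts: softmax per sample times depth per run
    z = log_abund - log_abund.max(axis=0, keepdims=True)
    prob = np.exp(z)
    prob /= prob.sum(axis=0, keepdims=True)
    mu = prob * spec.depth

    cols = {}
    rep_map: dict[str, list[str]] = {}
    for j, sid in enumerate(samples):
        rep_map[sid] = []
        for r in range(spec.n_replicates):
            col = f"{sid}.r{r + 1}"
            rep_map[sid].append(col)
            m = mu[:, j]
            if spec.noise == "poisson":
                draw = rng.poisson(m)
            else:
                lam = rng.gamma(shape=1.0 / spec.dispersion, scale=m * spec.dispersion)
                draw = rng.poisson(lam)
            cols[col] = draw.astype(np.int64)
    counts = pd.DataFrame(cols, index=proteins)
    truth = Truth(
        module_labels=pd.Series(module_labels, index=proteins, name="module"),
        module_links=module_links,
        differential=pd.DataFrame(diff_rows, columns=["protein", "group", "fold"]),
        expected_counts=pd.DataFrame(mu, index=proteins, columns=samples),
    )
    return SpectralCountMatrix(counts, rep_map), design, truth


def planted_module_ari(labels: pd.Series, truth: Truth) -> float:
    """Adjusted Rand index between recovered and planted labels, over the
    planted-module members.

    Background proteins are excluded because the assignment stage of the
    tree cut deliberately attaches them to nearby modules; module recovery
    is about whether the planted co-expression structure is found intact.
    """
    from sklearn.metrics import adjusted_rand_score

    planted = truth.module_labels[truth.module_labels > 0]
    common = [p for p in planted.index if p in labels.index]
    if not common:
        raise LepinetError("no planted module members in the label vector")
    return float(adjusted_rand_score(planted.loc[common], labels.loc[common]))


def recovered_module_of(labels: pd.Series, truth: Truth, planted_id: int) -> int | None:
    """The recovered module holding the majority of a planted module's
    members, or None if no module does (label 0 never matches)."""
    members = truth.module_labels.index[truth.module_labels == planted_id]
    members = [p for p in members if p in labels.index]
    if not members:
        return None
    counts = labels.loc[members].value_counts()
    top = int(counts.idxmax())
    if top == 0 or counts.max() <= len(members) / 2:
        return None
    return top


def simulate_network(
    n_nodes: int,
    model: str = "planted_cliques",
    clique_sizes: tuple[int, ...] = (6,),
    background_p: float = 0.05,
    seed: int = 0,
) -> tuple[nx.Graph, dict]:
    """Random PPI-like test networks with known hub structure.

    ``planted_cliques`` embeds disjoint cliques of the stated sizes on a
    sparse Erdos-Renyi background; the truth dict lists the planted members.
    ``erdos_renyi`` is the plain background model.
    """
    if model not in ("planted_cliques", "erdos_renyi"):
        raise LepinetError(f"unknown network model {model!r}")
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, background_p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in range(n_nodes)})
    g.add_nodes_from(f"N{i:03d}" for i in range(n_nodes))
    truth: dict = {"model": model, "cliques": []}
    if model == "planted_cliques":
        if sum(clique_sizes) > n_nodes:
            raise LepinetError("clique sizes exceed n_nodes")
        order = rng.permutation(n_nodes)
        cursor = 0
        for size in clique_sizes:
            members = [f"N{i:03d}" for i in order[cursor : cursor + size]]
            cursor += size
            for i in range(size):
                for j in range(i + 1, size):
                    g.add_edge(members[i], members[j])
            truth["cliques"].append(sorted(members))
    return g, truth
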