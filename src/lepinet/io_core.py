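"""Domain types and tabular I/O.

All on-disk artifacts are plain TSV (UTF-8, tab-separated, ``.`` decimal,
mandatory header row) so that a write/read round trip is bit-exact.  Run
manifests are JSON; dendrograms are exported as Newick strings.

The central container is :class:`SpectralCountMatrix`: a protein x sample
(optionally x replicate-run) table of non-negative integer spectral counts,
where a spectral count is the number of tandem MS/MS spectra assigned to a
protein in one LC-MS/MS run — the label-free abundance proxy used throughout
the pipeline.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lepinet")

_INT_RE = re.compile(r"^[+]?\d+$")


class LepinetError(ValueError):
    """Raised for malformed or inconsistent input artifacts."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpectralCountMatrix:
    """Protein x column matrix of non-negative integer spectral counts.

    ``counts`` columns are either bare sample ids, or ``sample.rep`` replicate
    runs; in the latter case ``replicate_map`` maps each sample id to its run
    columns (in column order).
    """

    counts: pd.DataFrame
    replicate_map: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise LepinetError("count matrix is empty")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise LepinetError(f"duplicate protein ids: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise LepinetError(f"duplicate column ids: {dup}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise LepinetError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise LepinetError(
                f"negative count at protein {df.index[i]!r}, column {df.columns[j]!r}"
            )
        if self.replicate_map is not None:
            for sample, cols in self.replicate_map.items():
                if len(cols) < 1:
                    raise LepinetError(f"sample {sample!r} has no replicate column")
                missing = [c for c in cols if c not in df.columns]
                if missing:
                    raise LepinetError(f"replicate columns {missing} missing for {sample!r}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        if self.replicate_map is not None:
            return list(self.replicate_map)
        return list(self.counts.columns)

    @property
    def has_replicates(self) -> bool:
        return self.replicate_map is not None


@dataclass
class GroupDesign:
    """Sample -> subtype assignment with derived one-vs-rest trait vectors.

    ``trait_vectors`` is a samples x groups 0/1 frame: column g is the binary
    clinical-trait encoding of membership in subtype g (e.g. AIS/MIA/LPA).
    """

    groups: pd.Series  # index: sample_id, values: group label
    trait_vectors: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if self.groups.index.duplicated().any():
            raise LepinetError("duplicate sample ids in design")
        if self.groups.isna().any():
            raise LepinetError("missing group label")
        labels = list(dict.fromkeys(self.groups))  # first-appearance order
        tv = pd.DataFrame(
            {g: (self.groups == g).astype(int) for g in labels}, index=self.groups.index
        )
        self.trait_vectors = tv
        for g in labels:
            if int(tv[g].sum()) < 2:
                logger.warning("group %r has < 2 samples; pairwise analyses will refuse it", g)

    @property
    def group_labels(self) -> list[str]:
        return list(self.trait_vectors.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    def samples_of(self, group: str) -> list[str]:
        if group not in self.trait_vectors.columns:
            raise LepinetError(f"unknown group {group!r}")
        return list(self.groups.index[self.groups == group])

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_of(g)) for g in self.group_labels}


@dataclass
class CopyNumberMatrix:
    """Gene x sample copy-number values; 2 means diploid."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            raise LepinetError("duplicate gene ids in copy-number matrix")
        if df.columns.duplicated().any():
            raise LepinetError("duplicate sample ids in copy-number matrix")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise LepinetError("non-finite copy-number value")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise LepinetError(
                f"negative copy number at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )


@dataclass
class MutationTable:
    """Rows of (sample_id, gene, variant_class[, protein_change])."""

    rows: pd.DataFrame

    REQUIRED = ("sample_id", "gene", "variant_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise LepinetError(f"mutation table missing columns {missing}")

    @classmethod
    def empty(cls) -> "MutationTable":
        return cls(pd.DataFrame(columns=list(cls.REQUIRED)))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", **kw)
    except pd.errors.EmptyDataError as exc:
        raise LepinetError(f"empty file: {path}") from exc
    if df.shape[0] == 0 and df.shape[1] <= 1:
        raise LepinetError(f"empty file: {path}")
    return df


def read_count_matrix(path, replicate_mode: str = "none") -> SpectralCountMatrix:
    """Read a spectral-count TSV (first column = protein id).

    With ``replicate_mode='columns'`` header names are parsed as
    ``sample.rep`` and grouped into per-sample replicate runs.
    """
    if replicate_mode not in ("none", "columns"):
        raise LepinetError(f"unknown replicate_mode {replicate_mode!r}")
    raw = _read_tsv(path, dtype=str)
    raw = raw.set_index(raw.columns[0])
    cols = {}
    for col in raw.columns:
        vals = raw[col].astype("string").str.strip()
        ok = vals.notna() & vals.str.fullmatch(r"\+?\d+")
        if not ok.all():
            pid = raw.index[~ok][0]
            bad = raw.loc[pid, col]
            raise LepinetError(
                f"count {bad!r} at protein {pid!r}, column {col!r} "
                "is not a non-negative integer"
            )
        cols[col] = vals.astype(np.int64)
    ints = pd.DataFrame(cols, index=raw.index)
    rep_map = None
    if replicate_mode == "columns":
        rep_map = {}
        for col in ints.columns:
            if "." not in col:
                raise LepinetError(f"column {col!r} lacks 'sample.rep' replicate naming")
            sample = col.rsplit(".", 1)[0]
            rep_map.setdefault(sample, []).append(col)
    return SpectralCountMatrix(ints, rep_map)


def read_sample_metadata(path, counts: SpectralCountMatrix) -> GroupDesign:
    """Read sample metadata (columns ``sample_id``, ``group``) and check that
    the sample set exactly matches the count matrix."""
    df = _read_tsv(path, dtype=str)
    for c in ("sample_id", "group"):
        if c not in df.columns:
            raise LepinetError(f"metadata missing column {c!r}")
    meta_samples = list(df["sample_id"])
    mat_samples = counts.sample_ids
    extra = sorted(set(meta_samples) - set(mat_samples))
    absent = sorted(set(mat_samples) - set(meta_samples))
    if extra or absent:
        raise LepinetError(
            f"sample mismatch between metadata and counts: "
            f"only in metadata {extra}, only in counts {absent}"
        )
    groups = pd.Series(df["group"].values, index=meta_samples, name="group")
    # preserve count-matrix sample order
    return GroupDesign(groups.loc[mat_samples])


def read_edge_list(path, score_min: float = 0.0):
    """Read a PPI edge list (``nodeA<TAB>nodeB[<TAB>score]``) into a simple
    undirected :class:`networkx.Graph`.

    Edges scoring below ``score_min`` (e.g. the STRING medium-confidence
    cutoff 0.400) are dropped at load; self-loops are dropped with a warning.
    """
    import networkx as nx

    if not 0.0 <= score_min <= 1.0:
        raise LepinetError("score_min must be in [0, 1]")
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise LepinetError(f"empty file: {path}")
        has_score = len(header.rstrip("\n").split("\t")) >= 3
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise LepinetError(f"{path}: malformed edge row at line {lineno}")
            a, b = parts[0], parts[1]
            score = None
            if has_score:
                if len(parts) < 3:
                    raise LepinetError(f"{path}: missing score at line {lineno}")
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise LepinetError(f"{path}: bad score at line {lineno}") from exc
                if not 0.0 <= score <= 1.0:
                    raise LepinetError(f"{path}: score outside [0,1] at line {lineno}")
            if a == b:
                logger.warning("dropping self-loop %r at line %d", a, lineno)
                continue
            if score is not None and score < score_min:
                continue
            if score is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, score=score)
    return g


def read_genomic_tables(cn_path, mut_path=None) -> tuple[CopyNumberMatrix, MutationTable]:
    """Read a gene x sample copy-number TSV and an optional mutation TSV."""
    cn_raw = _read_tsv(cn_path)
    cn_raw = cn_raw.set_index(cn_raw.columns[0])
    cn = CopyNumberMatrix(cn_raw.astype(float))
    if mut_path is None:
        return cn, MutationTable.empty()
    mut = MutationTable(_read_tsv(mut_path, dtype=str))
    return cn, mut


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path, *, command: str, params: dict, seed: int | None = None) -> None:
    """Write a JSON run manifest (command, parameters, seed, versions)."""
    import networkx
    import scipy
    import sklearn

    manifest = {
        "command": command,
        "params": params,
        "seed": seed,
        "versions": {
            "lepinet": _version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _version() -> str:
    from lepinet import __version__

    return __version__


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height(node)
        if node < n:
            return f"{labels[node]}:{bl:.6g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

    root = 2 * n - 2
    h = height(root)
    left, right = int(Z[root - n, 0]), int(Z[root - n, 1])
    return f"({render(left, h)},{render(right, h)});"
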