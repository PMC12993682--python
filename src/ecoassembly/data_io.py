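"""Reading, writing and transforming community abundance data.

The central container is :class:`CommunityMatrix`, a thin wrapper around a
samples x taxa :class:`pandas.DataFrame` that tracks whether values are
relative abundances, pseudo-counts, or a variance-stabilising transform of
relative abundances, together with optional per-sample metadata (digester,
phase).  Readers cover plain TSV tables and MetaPhlAn-style merged profiles
(clade strings such as ``k__...|s__...`` with values on a 0-100 scale); tree
input is Newick via scikit-bio.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CommunityMatrix",
    "PhaseTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_metaphlan_merged",
    "read_newick",
    "write_newick",
    "harmonize_taxa",
    "hellinger_transform",
    "to_pseudocounts",
    "read_phase_table",
    "write_phase_table",
]

_RANK_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}


@dataclass
class CommunityMatrix:
    """Samples x taxa abundance table.

    Parameters
    ----------
    data :
        DataFrame with sample identifiers as the index and taxon identifiers
        as columns; all values non-negative and finite.
    mode :
        ``"relative"`` (rows sum to 1), ``"pseudocount"`` (non-negative
        integers) or ``"transformed"`` (e.g. Hellinger; no row-sum contract).
    sample_meta :
        Optional DataFrame indexed by sample id with columns such as
        ``digester`` and ``phase``.
    """

    data: pd.DataFrame
    mode: str = "relative"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if self.mode not in {"relative", "pseudocount", "transformed"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.data.shape[0] == 0:
            raise ValueError("no samples")
        if self.data.shape[1] == 0:
            raise ValueError("no taxa")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon identifiers: {dupes}")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite or missing abundance values")
        if (vals < 0).any():
            raise ValueError("negative abundance values")
        if self.mode == "relative":
            rowsums = vals.sum(axis=1)
            if np.any(np.abs(rowsums - 1.0) > 1e-6):
                bad = self.data.index[np.abs(rowsums - 1.0) > 1e-6].tolist()
                raise ValueError(f"relative rows do not sum to 1: {bad}")
        elif self.mode == "pseudocount":
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("pseudocount mode requires integer values")
        if self.sample_meta is not None:
            missing = set(self.data.index) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    def copy_with(self, data: pd.DataFrame, mode: str | None = None) -> "CommunityMatrix":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[self.sample_meta.index.intersection(data.index)]
        return CommunityMatrix(data=data, mode=mode or self.mode, sample_meta=meta)


@dataclass
class PhaseTable:
    """Digester x phase physicochemical measurements.

    ``data`` is indexed by a (digester, phase) MultiIndex; columns are the
    measured parameters (volatile fatty acids in mg/L, pH, ammoniacal
    nitrogen, chemical oxygen demand, biochemical methane potential,
    methane percentage).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate (digester, phase) rows")
        if "pH" in self.data.columns:
            ph = self.data["pH"].to_numpy(dtype=float)
            if np.any((ph <= 0) | (ph >= 14)):
                raise ValueError("pH out of (0, 14)")
        conc = self.data.drop(columns=[c for c in ("pH",) if c in self.data.columns])
        if (conc.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative concentration values")

    def value(self, digester: str, phase: str, parameter: str) -> float:
        return float(self.data.loc[(digester, phase), parameter])

    def phase_groups(self, parameter: str) -> dict[str, np.ndarray]:
        """Values of one parameter grouped by phase (digesters as replicates)."""
        out: dict[str, np.ndarray] = {}
        for phase, sub in self.data.groupby(level="phase"):
            out[str(phase)] = sub[parameter].to_numpy(dtype=float)
        return out


def _normalize_rows(df: pd.DataFrame) -> pd.DataFrame:
    sums = df.sum(axis=1)
    if (sums <= 0).any():
        bad = df.index[sums <= 0].tolist()
        raise ValueError(f"empty sample (all-zero row): {bad}")
    return df.div(sums, axis=0)


def read_abundance_table(
    path: str | Path | io.TextIOBase,
    orientation: str = "samples_rows",
    mode: str = "relative",
    sample_meta: pd.DataFrame | None = None,
) -> CommunityMatrix:
    """Read a plain TSV abundance table into a :class:`CommunityMatrix`.

    ``orientation="taxa_rows"`` transposes on read.  For ``mode="relative"``
    rows are renormalized to sum to 1; ``mode="pseudocount"`` keeps integer
    counts as-is.
    """
    if orientation not in {"samples_rows", "taxa_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("no samples")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}") from exc
        raise
    if orientation == "taxa_rows":
        df = df.T
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    df.index.name = None
    df.columns.name = None
    if mode == "relative":
        df = _normalize_rows(df)
    return CommunityMatrix(data=df, mode=mode, sample_meta=sample_meta)


def write_abundance_table(matrix: CommunityMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out = out[sorted(out.columns)]
    out.sort_index().to_csv(path, sep="\t", index_label="sample_id")


def read_metaphlan_merged(path: str | Path, rank: str = "species") -> CommunityMatrix:
    """Read a MetaPhlAn-style merged profile, keeping rows at one rank.

    The first column is a clade string (``k__...|s__...``); remaining columns
    are samples with values on a 0-100 scale.  A leading ``#`` comment block
    and an optional NCBI-taxid second column are both tolerated.  Rows whose
    deepest rank is exactly `rank` are kept (for species: contains ``s__``
    but no strain-level ``t__``); the taxon id is the text after the rank
    prefix, values are divided by 100 and rows renormalized.
    """
    prefix = _RANK_PREFIX.get(rank)
    if prefix is None:
        raise ValueError(f"unknown rank {rank!r}")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[0] < 2:
        raise ValueError("no data rows in merged profile")
    header = df.iloc[0].tolist()
    body = df.iloc[1:].reset_index(drop=True)
    # taxid column sniff: second header field naming an NCBI taxid
    drop_second = len(header) > 2 and "taxid" in str(header[1]).lower().replace("_", "")
    clade = body.iloc[:, 0].astype(str)
    first_value_col = 2 if drop_second else 1
    sample_ids = [str(h).strip() for h in header[first_value_col:]]
    values = body.iloc[:, first_value_col:].astype(float)
    values.columns = sample_ids

    def deepest(c: str) -> str:
        last = c.split("|")[-1].strip()
        return last[:3]

    keep = clade.map(lambda c: deepest(c) == prefix)
    if not keep.any():
        raise ValueError(f"no rows at rank {rank!r}")
    vals = values.loc[keep.to_numpy()]
    if ((vals.to_numpy() < 0) | (vals.to_numpy() > 100)).any():
        raise ValueError("merged-profile value outside [0, 100]")
    taxa = clade[keep].map(lambda c: c.split("|")[-1].strip()[len(prefix):])
    df_out = vals.copy()
    df_out.index = taxa
    if df_out.index.duplicated().any():
        raise ValueError("duplicate taxa at requested rank")
    df_out = (df_out / 100.0).T  # samples x taxa
    df_out.index = df_out.index.astype(str)
    df_out = _normalize_rows(df_out)
    return CommunityMatrix(data=df_out, mode="relative")


def read_newick(source: str | Path | io.TextIOBase) -> TreeNode:
    """Read a rooted Newick tree with branch lengths, validating labels.

    Duplicate tip labels, missing branch lengths on non-root edges, and
    negative lengths are rejected.
    """
    if isinstance(source, (str, Path)) and not str(source).lstrip().startswith("("):
        tree = TreeNode.read(str(source), format="newick")
    elif isinstance(source, str):
        tree = TreeNode.read(io.StringIO(source), format="newick")
    else:
        tree = TreeNode.read(source, format="newick")
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if any(n is None for n in names):
        raise ValueError("tree has unlabeled tips")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.traverse():
        if node.is_root():
            continue
        if node.length is None:
            raise ValueError(f"missing branch length above {node.name or 'internal node'}")
        if node.length < 0:
            raise ValueError(f"negative branch length above {node.name or 'internal node'}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def harmonize_taxa(
    matrix: CommunityMatrix,
    tree: TreeNode,
    renormalize: bool = True,
) -> tuple[CommunityMatrix, TreeNode, dict]:
    """Restrict matrix and tree to their shared taxon set.

    Taxa absent from the tree (or tips absent from the matrix) are dropped so
    the community matrix and the phylogeny describe one consistent taxon set.
    Matching is exact string equality after trimming whitespace.  Relative
    rows are renormalized by default (configurable).  Returns the reduced
    matrix, the pruned tree, and a report listing dropped identifiers and the
    total relative abundance removed per sample.
    """
    tip_names = {t.name.strip() for t in tree.tips()}
    matrix_taxa = [t.strip() for t in matrix.taxon_ids]
    shared = [t for t in matrix_taxa if t in tip_names]
    if not shared:
        raise ValueError("no shared taxa between matrix and tree")
    dropped_taxa = [t for t in matrix_taxa if t not in tip_names]
    dropped_tips = sorted(tip_names - set(matrix_taxa))

    df = matrix.data.copy()
    df.columns = matrix_taxa
    removed = df[dropped_taxa].sum(axis=1) if dropped_taxa else pd.Series(0.0, index=df.index)
    df = df[shared]
    if matrix.mode == "relative" and renormalize:
        df = _normalize_rows(df)
    new_matrix = matrix.copy_with(df)

    if dropped_tips:
        new_tree = tree.shear(shared)
        new_tree.prune()
    else:
        new_tree = tree
    report = {
        "dropped_matrix_taxa": dropped_taxa,
        "dropped_tree_tips": dropped_tips,
        "removed_abundance_per_sample": removed.to_dict(),
        "n_shared": len(shared),
        "renormalized": bool(matrix.mode == "relative" and renormalize),
    }
    return new_matrix, new_tree, report


def hellinger_transform(matrix: CommunityMatrix) -> CommunityMatrix:
    """Square-root of row-normalized relative abundances.

    The Hellinger transform moderates the influence of dominant taxa in
    downstream distance and correlation computations.  Output rows no longer
    sum to 1 (their squares do), so the result is flagged ``transformed``.
    """
    if matrix.mode != "relative":
        raise ValueError("hellinger_transform requires mode='relative'; normalize first")
    df = _normalize_rows(matrix.data)
    return matrix.copy_with(np.sqrt(df), mode="transformed")


def to_pseudocounts(matrix: CommunityMatrix, depth: int = 10_000) -> CommunityMatrix:
    """Convert relative abundances to integer pseudo-counts at a fixed depth.

    Each row is scaled by `depth` and rounded; taxa with positive relative
    abundance that would round to 0 are floored to 1 so presence/absence is
    preserved exactly.  The default depth keeps taxa at the 0.02% level
    represented by at least 2 counts.
    """
    if matrix.mode != "relative":
        raise ValueError("to_pseudocounts requires mode='relative'")
    if depth < 1:
        raise ValueError("depth must be a positive integer")
    vals = matrix.values
    richness = (vals > 0).sum(axis=1)
    if (depth < richness).any():
        bad = matrix.data.index[depth < richness].tolist()
        raise ValueError(f"depth {depth} cannot represent all presences in samples {bad}")
    counts = np.round(vals * depth)
    counts[(vals > 0) & (counts == 0)] = 1
    df = pd.DataFrame(counts.astype(int), index=matrix.data.index, columns=matrix.data.columns)
    return matrix.copy_with(df, mode="pseudocount")


def read_phase_table(path: str | Path) -> PhaseTable:
    """Read a long-format CSV with columns digester,phase,parameter,value."""
    df = pd.read_csv(path)
    required = {"digester", "phase", "parameter", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phase table needs columns {sorted(required)}")
    wide = df.pivot_table(
        index=["digester", "phase"], columns="parameter", values="value", aggfunc="first"
    )
    wide.columns.name = None
    return PhaseTable(data=wide)


def write_phase_table(table: PhaseTable, path: str | Path) -> None:
    long = (
        table.data.stack()
        .rename("value")
        .reset_index()
        .rename(columns={"level_2": "parameter"})
    )
    long.columns = ["digester", "phase", "parameter", "value"]
    long.sort_values(["digester", "phase", "parameter"]).to_csv(path, index=False)
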