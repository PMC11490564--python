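"""Count tables, phylogenies and sample metadata.

The universal inputs of the toolkit are (i) a samples x ASVs integer count
table per kingdom, (ii) a rooted phylogeny whose tips cover the ASV ids and
(iii) a per-sample metadata table carrying the sampling day, the granulation
stage and the reactor measurements. This module reads and validates those
three objects and provides the preprocessing steps every analysis starts
from: rarefaction to even depth, prevalence/abundance filtering and stage
labelling by day.
"""
from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "STAGES",
    "DEFAULT_STAGE_BOUNDARIES",
    "CountTable",
    "PhyloTree",
    "EnvTable",
    "assign_stage",
    "load_dataset",
    "rarefy",
    "filter_prevalence_abundance",
]

#: Granulation stages in temporal order.
STAGES = ("floccular", "intermediate", "granular")

#: First day of the intermediate and granular stages. Days 0-15 are
#: floccular, 16-115 intermediate, 116 onward granular.
DEFAULT_STAGE_BOUNDARIES = (16.0, 116.0)


def assign_stage(day: float, boundaries=DEFAULT_STAGE_BOUNDARIES) -> str:
    """Map a sampling day to its granulation stage.

    The default boundaries split the reactor run into the floccular
    (days 0-15), intermediate (16-115) and granular (>=116) stages; the
    intervals are half-open, so day 16 is intermediate and day 116 granular.
    """
    if day < 0:
        raise ValueError(f"day must be non-negative, got {day}")
    lo, hi = boundaries
    if not lo < hi:
        raise ValueError("stage boundaries must be increasing")
    if day < lo:
        return "floccular"
    if day < hi:
        return "intermediate"
    return "granular"


@dataclass
class CountTable:
    """Samples x ASVs read-count matrix for one kingdom.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers (ascending by day when days are given).
    asv_ids : list of str
        Unique ASV identifiers, one per column of ``counts``.
    counts : ndarray of int, shape (n_samples, n_asvs)
        Non-negative read counts.
    kingdom : {"prokaryote", "eukaryote"}
    days : ndarray of float, optional
        Sampling day of each sample; strictly increasing when present.
    """

    sample_ids: list
    asv_ids: list
    counts: np.ndarray
    kingdom: str = "prokaryote"
    days: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x ASVs)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise ValueError("duplicate ASV ids")
        if self.kingdom not in ("prokaryote", "eukaryote"):
            raise ValueError(f"unknown kingdom {self.kingdom!r}")
        totals = self.counts.sum(axis=1)
        if np.any(totals == 0):
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"samples with zero total reads: {empty}")
        if self.days is not None:
            self.days = np.asarray(self.days, dtype=float)
            if len(self.days) != len(self.sample_ids):
                raise ValueError("days length must match sample count")
            if np.any(np.diff(self.days) <= 0):
                raise ValueError("days must be strictly increasing")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def totals(self) -> np.ndarray:
        """Per-sample read totals."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-closed relative abundances (each sample sums to 1)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def presence(self) -> np.ndarray:
        """Boolean presence matrix (count > 0)."""
        return self.counts > 0

    def stage_of(self, boundaries=DEFAULT_STAGE_BOUNDARIES) -> list:
        if self.days is None:
            raise ValueError("table carries no day mapping")
        return [assign_stage(d, boundaries) for d in self.days]

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: first column ``sample_id``, then one column per ASV."""
        df = pd.DataFrame(self.counts, columns=self.asv_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, kingdom="prokaryote", days=None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "sample_id":
            # tolerate an unnamed first column
            df = df.rename(columns={df.columns[0]: "sample_id"})
        sample_ids = df["sample_id"].astype(str).tolist()
        asv_ids = [c for c in df.columns if c != "sample_id"]
        counts = df[asv_ids].to_numpy()
        if not np.all(counts == np.floor(counts)):
            raise ValueError(f"non-integer counts in {path}")
        return cls(sample_ids, asv_ids, counts, kingdom=kingdom, days=days)

    @classmethod
    def from_biom_json(cls, path, kingdom="prokaryote", days=None) -> "CountTable":
        """Read a BIOM 1.0 (JSON) table; rows are observations (ASVs)."""
        with open(path) as fh:
            doc = json.load(fh)
        asv_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape)
        if doc.get("matrix_type", "dense") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat = np.asarray(doc["data"], dtype=float)
        if not np.all(mat == np.floor(mat)):
            raise ValueError(f"non-integer counts in {path}")
        # BIOM stores observations x samples; transpose to samples x ASVs
        return cls(sample_ids, asv_ids, mat.T.astype(np.int64), kingdom=kingdom, days=days)


@dataclass
class PhyloTree:
    """Rooted phylogeny with branch lengths; tips are ASV ids."""

    tree: TreeNode
    _dm_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        tips = self.tip_names()
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels")

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        """Parse a newick file path or string."""
        text = str(source)
        looks_like_newick = "(" in text or ";" in text
        p = Path(text) if not looks_like_newick and len(text) < 4096 else None
        if p is not None and p.exists():
            tree = TreeNode.read(str(p), format="newick")
        else:
            tree = TreeNode.read(io.StringIO(text), format="newick")
        return cls(tree)

    def to_newick(self, path=None) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        s = buf.getvalue()
        if path is not None:
            Path(path).write_text(s)
        return s

    def tip_names(self) -> list:
        return [t.name for t in self.tree.tips()]

    def cophenetic(self, asv_ids=None) -> np.ndarray:
        """Pairwise tip-to-tip patristic distance matrix.

        When ``asv_ids`` is given the matrix is returned in that order
        (must be a subset of the tip set).
        """
        key = tuple(asv_ids) if asv_ids is not None else None
        if key in self._dm_cache:
            return self._dm_cache[key]
        dm = self._dm_cache.get("__full__")
        if dm is None:
            dm = self.tree.tip_tip_distances()
            self._dm_cache["__full__"] = dm
        if asv_ids is None:
            out = np.asarray(dm.data, dtype=float)
        else:
            missing = [a for a in asv_ids if a not in set(dm.ids)]
            if missing:
                raise KeyError(f"ASVs not in tree: {missing}")
            idx = [dm.index(a) for a in asv_ids]
            out = np.asarray(dm.data, dtype=float)[np.ix_(idx, idx)]
        self._dm_cache[key] = out
        return out


@dataclass
class EnvTable:
    """Per-sample metadata: day, granulation stage and reactor measurements.

    ``frame`` is indexed by sample id and must contain a ``day`` column and a
    ``stage`` column; every remaining numeric column is treated as an
    environmental variable (e.g. nitrate mg/L, VSS g/L, phosphate, TOC).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        if "day" not in self.frame.columns:
            raise ValueError("EnvTable requires a 'day' column")
        if "stage" not in self.frame.columns:
            self.frame = self.frame.copy()
            self.frame["stage"] = [assign_stage(d) for d in self.frame["day"]]
        self.frame.index = self.frame.index.astype(str)
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        days = self.frame["day"].to_numpy(dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        bad = [s for s in self.frame["stage"] if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {sorted(set(bad))}")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def days(self) -> np.ndarray:
        return self.frame["day"].to_numpy(dtype=float)

    @property
    def stages(self) -> list:
        return list(self.frame["stage"])

    @property
    def variables(self) -> list:
        """Names of the environmental measurement columns."""
        return [
            c
            for c in self.frame.columns
            if c not in ("day", "stage")
            and np.issubdtype(self.frame[c].dtype, np.number)
        ]

    def values(self, variable: str) -> np.ndarray:
        if variable not in self.frame.columns:
            raise KeyError(f"variable {variable!r} not in metadata")
        v = self.frame[variable].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            raise ValueError(f"missing values in variable {variable!r}")
        return v

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "EnvTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df)


def load_dataset(table_path, tree_path, env_path, kingdom="prokaryote"):
    """Read and cross-validate a (count table, tree, metadata) triple.

    The count table may be TSV (``.tsv``/``.txt``) or BIOM 1.0 JSON
    (``.json``/``.biom``); the tree is newick; the metadata is CSV. Samples
    are ordered by day (the metadata order); validation fails hard when a
    table ASV is missing from the tree tips or when the sample sets differ.
    """
    env = EnvTable.from_csv(env_path)
    suffix = Path(table_path).suffix.lower()
    if suffix in (".json", ".biom"):
        table = CountTable.from_biom_json(table_path, kingdom=kingdom)
    else:
        table = CountTable.from_tsv(table_path, kingdom=kingdom)
    if set(table.sample_ids) != set(env.sample_ids):
        only_t = sorted(set(table.sample_ids) - set(env.sample_ids))
        only_e = sorted(set(env.sample_ids) - set(table.sample_ids))
        raise ValueError(
            f"sample mismatch between table and metadata: table-only={only_t}, "
            f"metadata-only={only_e}"
        )
    # reorder samples to metadata (day) order
    order = [table.sample_ids.index(s) for s in env.sample_ids]
    table = CountTable(
        env.sample_ids,
        table.asv_ids,
        table.counts[order],
        kingdom=kingdom,
        days=env.days,
    )
    tree = PhyloTree.from_newick(tree_path)
    tips = set(tree.tip_names())
    missing = sorted(set(table.asv_ids) - tips)
    if missing:
        raise ValueError(f"ASVs missing from tree tips: {missing}")
    return table, tree, env


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Uses multivariate hypergeometric draws per sample, reproducible for a
    fixed seed. Samples with fewer than ``depth`` reads are a hard error.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.totals()
    short = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if short:
        raise ValueError(f"samples with total reads below depth {depth}: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        if totals[i] == depth:
            out[i] = table.counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CountTable(
        table.sample_ids, table.asv_ids, out, kingdom=table.kingdom, days=table.days
    )


def filter_prevalence_abundance(
    table: CountTable,
    min_prevalence: float = 0.10,
    min_rel_abundance: float = 0.001,
) -> CountTable:
    """Drop rare ASVs: keep those present in at least ``min_prevalence`` of
    samples AND holding at least ``min_rel_abundance`` of the grand total
    read count. The sample set is unchanged.
    """
    prev = table.presence().mean(axis=0)
    share = table.counts.sum(axis=0) / table.counts.sum()
    keep = (prev >= min_prevalence) & (share >= min_rel_abundance)
    if not keep.any():
        raise ValueError(
            "prevalence/abundance filter removed every ASV; thresholds "
            "incompatible with the data"
        )
    asv_ids = [a for a, k in zip(table.asv_ids, keep) if k]
    return CountTable(
        table.sample_ids,
        asv_ids,
        table.counts[:, keep],
        kingdom=table.kingdom,
        days=table.days,
    )
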