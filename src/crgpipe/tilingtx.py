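"""Tiling-array transcriptomics: probe->ORF assignment, per-ORF expression,
differential expression with ESR filtering, and correlation-based clustering.

Probes are assigned to an ORF when the probe interval lies fully within the
ORF interval on the same chromosome (strand-agnostic by default — tiling
arrays interrogate both strands).  The log2 signal of an ORF on each array is
the unweighted mean over its assigned probes, quantile-normalized across
arrays before comparison.  Differential expression between drug and solvent
arrays uses log2(drug/DMSO) fold changes and a two-sided Student's t-test,
with up/down calls at |log2 fc| > 1 and P < 0.05; genes of the Environmental
Stress Response (ESR) — induced or repressed by almost any stress — are
flagged and excluded from downstream enrichment input so that only
drug-specific transcription remains.  Expression profiles are clustered
agglomeratively with distance 1 - Pearson r and unweighted average linkage
(UPGMA).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .barcode_fitness import quantile_normalize_frame

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass
class OrfIndex:
    """Interval index over ORFs keyed by chromosome (1-based inclusive)."""

    trees: dict[str, IntervalTree]
    orfs: pd.DataFrame  # orf_id, chrom, start, end, strand
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.orfs)


def load_orfs(gff: str, feature_types: set[str] | None = None) -> OrfIndex:
    """Build an ORF interval index from GFF3 text or a path to a GFF3 file.

    Coordinates are kept 1-based inclusive as in the GFF convention.
    Malformed lines are skipped and counted.
    """
    if "\n" not in gff:
        with open(gff) as fh:
            text = fh.read()
    else:
        text = gff
    rows = []
    n_skipped = 0
    for line in io.StringIO(text):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            n_skipped += 1
            continue
        chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
        if feature_types is not None and ftype not in feature_types:
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            n_skipped += 1
            continue
        if start_i > end_i:
            n_skipped += 1
            continue
        orf_id = None
        for kv in attrs.split(";"):
            if kv.startswith("ID="):
                orf_id = kv[3:]
                break
        if orf_id is None:
            n_skipped += 1
            continue
        rows.append((orf_id, chrom, start_i, end_i, strand))
    if n_skipped:
        logger.warning("skipped %d malformed GFF lines", n_skipped)
    orfs = pd.DataFrame(rows, columns=["orf_id", "chrom", "start", "end", "strand"])
    if orfs.empty:
        logger.warning("empty ORF index")
    trees: dict[str, IntervalTree] = {}
    for _, r in orfs.iterrows():
        # interval end is exclusive in intervaltree; +1 converts from inclusive
        trees.setdefault(r.chrom, IntervalTree()).addi(
            r.start, r.end + 1, (r.orf_id, r.strand)
        )
    return OrfIndex(trees=trees, orfs=orfs, n_skipped=n_skipped)


def assign_probes(
    probes: pd.DataFrame, index: OrfIndex, *, stranded: bool = False
) -> pd.DataFrame:
    """Map probes to ORFs by full containment on the same chromosome.

    ``probes`` needs columns ``probe_id``, ``chrom``, ``start``, ``end``,
    ``strand``.  A probe matching several overlapping ORFs is assigned to all
    of them with ``ambiguous`` True.
    """
    rows = []
    for r in probes.itertuples():
        tree = index.trees.get(r.chrom)
        if tree is None:
            continue
        matches = [
            iv.data
            for iv in tree.overlap(r.start, r.end + 1)
            if iv.begin <= r.start and iv.end >= r.end + 1
        ]
        if stranded:
            matches = [m for m in matches if m[1] == r.strand]
        for orf_id, _strand in matches:
            rows.append((r.probe_id, orf_id, len(matches) > 1))
    return pd.DataFrame(rows, columns=["probe_id", "orf_id", "ambiguous"])


def orf_expression(
    probes: pd.DataFrame,
    assignment: pd.DataFrame,
    *,
    min_probes: int = 1,
    normalize: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-ORF log2 expression: unweighted mean over assigned probes per array.

    Returns the ORF x array matrix (quantile-normalized across arrays unless
    ``normalize`` is False) and the per-ORF probe count.  ORFs with fewer than
    ``min_probes`` assigned probes are dropped and logged.
    """
    array_cols = [
        c for c in probes.columns
        if c not in ("probe_id", "chrom", "start", "end", "strand")
    ]
    merged = assignment.merge(probes[["probe_id", *array_cols]], on="probe_id")
    counts = merged.groupby("orf_id")["probe_id"].nunique()
    expr = merged.groupby("orf_id")[array_cols].mean()
    keep = counts[counts >= min_probes].index
    dropped = len(expr) - len(keep)
    if dropped:
        logger.warning("dropped %d ORFs with < %d probes", dropped, min_probes)
    expr = expr.loc[keep]
    if normalize and expr.shape[1] >= 2:
        expr = quantile_normalize_frame(expr)
    return expr, counts.loc[keep]


def differential_expression(
    orf_matrix: pd.DataFrame,
    design: dict[str, str],
    esr: set[str] | None = None,
    *,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-ORF log2(drug/DMSO), Student's t P, up/down call, ESR flag.

    ``design`` maps array id -> ``drug``/``control``.  With fewer than two
    replicates per condition the P-value is undefined and the record flagged.
    """
    drug_cols = [a for a, c in design.items() if c == "drug"]
    ctrl_cols = [a for a, c in design.items() if c == "control"]
    if not drug_cols or not ctrl_cols:
        raise ValueError("design must contain drug and control arrays")
    esr = esr or set()
    underpowered = len(drug_cols) < 2 or len(ctrl_cols) < 2

    rows = []
    for orf, row in orf_matrix.iterrows():
        d = row[drug_cols].to_numpy(dtype=float)
        c = row[ctrl_cols].to_numpy(dtype=float)
        log2fc = float(d.mean() - c.mean())  # values already on log2 scale
        if underpowered:
            p = float("nan")
        elif np.allclose(d, d[0]) and np.allclose(c, c[0]):
            p = 1.0 if np.isclose(log2fc, 0.0) else 0.0
        else:
            p = float(stats.ttest_ind(d, c).pvalue)
        if np.isfinite(p) and p < alpha and log2fc > fc_threshold:
            call = UP
        elif np.isfinite(p) and p < alpha and log2fc < -fc_threshold:
            call = DOWN
        else:
            call = NONE
        rows.append((orf, log2fc, p, call, orf in esr, underpowered))
    return pd.DataFrame(
        rows, columns=["orf", "log2fc", "p_value", "call", "esr_filtered", "flagged"]
    ).set_index("orf")


def enrichment_input(de: pd.DataFrame, direction: str | None = None) -> list[str]:
    """Called, non-ESR ORFs for downstream enrichment (optionally one direction)."""
    mask = de["call"] != NONE if direction is None else de["call"] == direction
    return sorted(de.index[mask & ~de["esr_filtered"]])


@dataclass
class ClusterTree:
    """Average-linkage dendrogram over profiles under d = 1 - Pearson r."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            inner = ",".join(fmt(ch, node.dist) for ch in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        return fmt(root, root.dist).rsplit(":", 1)[0] + ";"


def correlation_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson r between the rows of ``matrix``."""
    corr = np.corrcoef(matrix.to_numpy(dtype=float))
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def cluster_profiles(matrix: pd.DataFrame) -> ClusterTree:
    """UPGMA clustering of expression profiles; zero-variance rows dropped.

    Rows are sorted lexicographically first so tie-breaking is deterministic.
    """
    variances = matrix.var(axis=1, ddof=0)
    dropped = list(matrix.index[variances == 0])
    if dropped:
        logger.warning("dropped %d zero-variance profiles", len(dropped))
    work = matrix.loc[variances > 0].sort_index()
    if work.shape[0] < 2:
        raise ValueError("need at least two non-constant profiles to cluster")
    dist = correlation_distance_matrix(work)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ClusterTree(linkage=z, labels=list(work.index))
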