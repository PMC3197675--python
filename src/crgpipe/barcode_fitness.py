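"""Per-strain fitness-defect scores from pooled barcode hybridization intensities.

Pooled deletion strains carry unique 20-mer barcodes (an uptag and a dntag
flanking the deletion cassette).  After competitive growth in drug vs. solvent
control, barcode abundance is read out on a tag microarray.  This module turns
the raw tag-intensity matrix into per-strain fitness-defect scores

    f = log2(mean drug intensity / mean DMSO intensity)

so that a growth defect gives a negative score.  The processing chain is
quantile normalization across arrays, collapse of a strain's tags to one value
per array, single-pass omission of replicate outliers more than one sample
standard deviation from the replicate mean, score computation, and a per-strain
t-test (paired on replicate-wise log-ratios when replicate counts match,
otherwise unpaired on log2 intensities).

Strains are called ``sensitive`` when f < -1 with P < 0.05 and ``resistant``
when f > 1 with P < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DRUG = "drug"
CONTROL = "control"

SENSITIVE = "sensitive"
RESISTANT = "resistant"
NONE = "none"


@dataclass
class IntensityMatrix:
    """Tag x array intensity matrix with tag->strain map and array metadata.

    ``values``: DataFrame indexed by tag id, columns = array ids, non-negative.
    ``tag_to_strain``: Series mapping every tag id to exactly one strain id.
    ``arrays``: DataFrame indexed by array id with columns ``condition``
    (``drug``/``control``) and ``replicate``.
    """

    values: pd.DataFrame
    tag_to_strain: pd.Series
    arrays: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        missing = self.values.index.difference(self.tag_to_strain.index)
        if len(missing):
            raise ValueError(f"tags without a strain mapping: {list(missing)[:5]}")
        if not set(self.arrays["condition"]) <= {DRUG, CONTROL}:
            raise ValueError("array condition must be 'drug' or 'control'")
        for cond in (DRUG, CONTROL):
            if (self.arrays["condition"] == cond).sum() < 1:
                raise ValueError(f"need at least one {cond} array")

    def arrays_for(self, condition: str) -> list[str]:
        return list(self.arrays.index[self.arrays["condition"] == condition])


@dataclass
class FitnessRecord:
    strain_id: str
    score: float
    p_value: float
    n_drug_used: int
    n_control_used: int
    call: str
    flagged: bool = False


@dataclass
class FitnessTable:
    """One record per strain plus the between-replicate reproducibility r."""

    records: pd.DataFrame
    replicate_correlation: float = float("nan")

    def __post_init__(self) -> None:
        if self.records["strain_id"].duplicated().any():
            raise ValueError("duplicate strain in fitness table")

    def calls(self) -> pd.Series:
        return self.records.set_index("strain_id")["call"]

    def scores(self) -> pd.Series:
        return self.records.set_index("strain_id")["score"]


def quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of ``df``.

    The reference distribution is the vector of row means of the
    column-sorted data; each column's values are replaced by the reference
    value at their rank, tied ranks receiving the mean of the tied reference
    values (linear interpolation at the average rank).
    """
    if df.shape[1] < 2:
        logger.warning("quantile normalization of a single column is the identity")
        return df.copy()
    arr = df.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(arr.shape[0], dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize an intensity matrix across arrays (input unmodified)."""
    return IntensityMatrix(
        values=quantile_normalize_frame(matrix.values),
        tag_to_strain=matrix.tag_to_strain,
        arrays=matrix.arrays,
    )


def summarize_tags_to_strains(matrix: IntensityMatrix) -> pd.DataFrame:
    """Collapse uptag/dntag rows to one row per strain (mean over tags)."""
    strains = matrix.tag_to_strain.loc[matrix.values.index]
    counts = strains.value_counts()
    if (counts < 1).any():  # defensive; value_counts cannot produce 0
        raise ValueError("strain with zero tags")
    grouped = matrix.values.groupby(strains).mean()
    grouped.index.name = "strain_id"
    return grouped


def omit_outliers(values: list[float] | np.ndarray) -> np.ndarray:
    """Drop replicate values more than one sample SD from the mean (one pass).

    Lists of length <= 2 are returned unchanged; the retained list is never
    empty (at least one value always lies within one SD of the mean).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty replicate list")
    if arr.size <= 2:
        return arr
    sd = arr.std(ddof=1)
    if sd == 0:
        return arr
    keep = np.abs(arr - arr.mean()) <= sd
    return arr[keep]


def _floor_zeros(frame: pd.DataFrame, pseudocount: float | None) -> pd.DataFrame:
    positive = frame.to_numpy()[frame.to_numpy() > 0]
    if pseudocount is None:
        pseudocount = positive.min() / 2.0 if positive.size else 1.0
    return frame.clip(lower=pseudocount)


def _replicate_correlation(log_drug: pd.DataFrame, log_ctrl: pd.DataFrame) -> float:
    """Mean pairwise Pearson r between per-replicate score vectors."""
    n = min(log_drug.shape[1], log_ctrl.shape[1])
    if n < 2:
        return float("nan")
    vectors = [
        log_drug.iloc[:, i].to_numpy() - log_ctrl.iloc[:, i].to_numpy()
        for i in range(n)
    ]
    rs = []
    for i in range(n):
        for j in range(i + 1, n):
            if vectors[i].std() == 0 or vectors[j].std() == 0:
                continue  # constant score vector: correlation undefined
            rs.append(np.corrcoef(vectors[i], vectors[j])[0, 1])
    return float(np.mean(rs)) if rs else float("nan")


def fitness_scores(
    strain_values: pd.DataFrame,
    arrays: pd.DataFrame,
    *,
    score_threshold: float = 1.0,
    alpha: float = 0.05,
    omit: bool = True,
    pseudocount: float | None = None,
) -> FitnessTable:
    """Score every strain: f = log2(mean_drug / mean_control), t-test P-value.

    ``strain_values`` is a strain x array matrix (tags already collapsed);
    ``arrays`` carries the drug/control condition per array.  Outlier
    replicates are omitted per strain per condition before the means.  Strains
    whose post-floor means are non-positive are flagged rather than dropped.
    """
    drug_cols = list(arrays.index[arrays["condition"] == DRUG])
    ctrl_cols = list(arrays.index[arrays["condition"] == CONTROL])
    if not drug_cols or not ctrl_cols:
        raise ValueError("need at least one drug and one control array")

    floored = _floor_zeros(strain_values, pseudocount)
    records = []
    paired = len(drug_cols) == len(ctrl_cols)
    for strain, row in floored.iterrows():
        drug = row[drug_cols].to_numpy(dtype=float)
        ctrl = row[ctrl_cols].to_numpy(dtype=float)
        drug_kept = omit_outliers(drug) if omit else drug
        ctrl_kept = omit_outliers(ctrl) if omit else ctrl
        mean_d, mean_c = drug_kept.mean(), ctrl_kept.mean()
        flagged = mean_d <= 0 or mean_c <= 0
        score = float(np.log2(mean_d / mean_c)) if not flagged else float("nan")

        if paired and len(drug) >= 2:
            diffs = np.log2(drug) - np.log2(ctrl)
            if np.allclose(diffs, diffs[0]):
                p = 1.0 if np.allclose(diffs, 0) else 0.0
            else:
                p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
        elif len(drug_kept) >= 2 and len(ctrl_kept) >= 2:
            p = float(
                stats.ttest_ind(np.log2(drug_kept), np.log2(ctrl_kept)).pvalue
            )
        else:
            p = float("nan")

        call = classify_fitness(score, p, score_threshold=score_threshold, alpha=alpha)
        records.append(
            (strain, score, p, len(drug_kept), len(ctrl_kept), call, flagged)
        )

    table = pd.DataFrame(
        records,
        columns=[
            "strain_id",
            "score",
            "p_value",
            "n_drug_used",
            "n_control_used",
            "call",
            "flagged",
        ],
    )
    log_d = np.log2(floored[drug_cols])
    log_c = np.log2(floored[ctrl_cols])
    return FitnessTable(records=table, replicate_correlation=_replicate_correlation(log_d, log_c))


def classify_fitness(
    score: float,
    p_value: float,
    *,
    score_threshold: float = 1.0,
    alpha: float = 0.05,
) -> str:
    """sensitive iff score < -threshold and p < alpha; resistant iff score > +threshold."""
    if not np.isfinite(score) or not np.isfinite(p_value):
        return NONE
    if score < -score_threshold and p_value < alpha:
        return SENSITIVE
    if score > score_threshold and p_value < alpha:
        return RESISTANT
    return NONE


def pool_fitness(
    matrix: IntensityMatrix,
    *,
    normalize: bool = True,
    score_threshold: float = 1.0,
    alpha: float = 0.05,
    omit: bool = True,
) -> FitnessTable:
    """Full chain: quantile normalize -> collapse tags -> score -> classify."""
    mat = quantile_normalize(matrix) if normalize else matrix
    strain_values = summarize_tags_to_strains(mat)
    return fitness_scores(
        strain_values, mat.arrays, score_threshold=score_threshold, alpha=alpha, omit=omit
    )


def read_intensity_tsv(path) -> IntensityMatrix:
    """Read the long-format tag-intensity TSV (synthio dialect)."""
    long = pd.read_csv(path, sep="\t")
    required = {"tag_id", "strain_id", "array_id", "condition", "replicate", "intensity"}
    if not required <= set(long.columns):
        raise ValueError(f"intensity TSV must have columns {sorted(required)}")
    values = long.pivot(index="tag_id", columns="array_id", values="intensity")
    tag_map = long.drop_duplicates("tag_id").set_index("tag_id")["strain_id"]
    arrays = (
        long.drop_duplicates("array_id")
        .set_index("array_id")[["condition", "replicate"]]
    )
    # keep the file's array order rather than pivot's lexicographic one
    values = values[arrays.index]
    return IntensityMatrix(values=values, tag_to_strain=tag_map, arrays=arrays)


def write_fitness_tsv(table: FitnessTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_fitness_tsv(path) -> FitnessTable:
    return FitnessTable(records=pd.read_csv(path, sep="\t"))
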