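"""Comparative lipidomics and qPCR relative quantification.

Lipidomics: MRM ion intensities are normalized to class-matched internal
standards within each sample, drug responses are expressed as
log2(drug/DMSO) of the normalized group means, and per-species significance
is assessed with the Kruskal-Wallis rank test (chi-square approximation, with
an exact label-permutation option for small samples).  Species are described
by a compact grammar ``CLASS[-HYDROXYL] CARBONS:DOUBLEBONDS`` (e.g. ``PI 34:1``,
``IPC-C 44:0``); the -B/-C/-D suffixes on sphingolipids denote two, three and
four hydroxyl groups.  Chain-length stratification calls species short or
long at a configurable total-acyl-carbon cutoff (default 32, i.e. C16+C16)
and flags fully saturated species.

qPCR: the 2^-ddCt method.  dCt = Ct_target - Ct_reference per sample,
ddCt = mean dCt(condition) - mean dCt(calibrator), fold = 2^-ddCt.  Tests run
on the dCt scale: paired t for within-strain treatment contrasts, unpaired t
for between-strain contrasts.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: sphingolipid classes that may carry a -B/-C/-D hydroxylation suffix
SPHINGOLIPID_CLASSES = {"IPC", "MIPC", "M(IP)2C", "Cer"}

_HYDROXYL_SUFFIX = {"B": 2, "C": 3, "D": 4}
_SUFFIX_FOR = {v: k for k, v in _HYDROXYL_SUFFIX.items()}

_SPECIES_RE = re.compile(
    r"^(?P<cls>[A-Za-z0-9()]+?)(?:-(?P<hyd>[BCD]))?\s+(?P<c>\d+):(?P<db>\d+)$"
)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid identity: class, total acyl carbons, double bonds, hydroxylation."""

    lipid_class: str
    carbons: int
    double_bonds: int
    hydroxyls: int | None = None

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise ValueError("carbons must be positive")
        if self.double_bonds < 0:
            raise ValueError("double bonds must be >= 0")
        if self.hydroxyls is not None and self.lipid_class not in SPHINGOLIPID_CLASSES:
            raise ValueError(
                f"hydroxylation suffix only valid for sphingolipid classes, not {self.lipid_class}"
            )

    @property
    def name(self) -> str:
        cls = self.lipid_class
        if self.hydroxyls is not None:
            cls = f"{cls}-{_SUFFIX_FOR[self.hydroxyls]}"
        return f"{cls} {self.carbons}:{self.double_bonds}"

    @property
    def saturated(self) -> bool:
        return self.double_bonds == 0


def parse_species(text: str) -> LipidSpecies:
    """Parse a ``CLASS[-HYDROXYL] C:DB`` descriptor like ``IPC-C 44:0``."""
    m = _SPECIES_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse lipid species descriptor: {text!r}")
    hyd = m.group("hyd")
    return LipidSpecies(
        lipid_class=m.group("cls"),
        carbons=int(m.group("c")),
        double_bonds=int(m.group("db")),
        hydroxyls=_HYDROXYL_SUFFIX[hyd] if hyd else None,
    )


@dataclass
class DiffAbundanceRecord:
    species: LipidSpecies
    group_means: dict[str, float]
    log2_response: float
    h_statistic: float
    p_value: float
    significant: bool


def normalize_to_standards(
    intensities: pd.DataFrame, standards: pd.DataFrame
) -> pd.DataFrame:
    """Divide each species' intensity by its class standard in the same sample.

    ``intensities``: species-name x sample; ``standards``: lipid-class x sample.
    """
    out = {}
    for name, row in intensities.iterrows():
        cls = parse_species(str(name)).lipid_class
        if cls not in standards.index:
            raise ValueError(f"no internal standard for class {cls} (species {name})")
        std = standards.loc[cls]
        for sample in intensities.columns:
            if sample not in std.index or not np.isfinite(std[sample]) or std[sample] == 0:
                raise ValueError(
                    f"missing or zero standard for class {cls}, sample {sample}"
                )
        out[name] = row / std[intensities.columns]
    normed = pd.DataFrame.from_dict(out, orient="index")
    normed.index.name = intensities.index.name
    return normed.loc[intensities.index]


def lipid_log2_response(
    normalized: pd.DataFrame,
    design: dict[str, str],
    *,
    drug_group: str = "drug",
    control_group: str = "DMSO",
) -> pd.Series:
    """log2(mean drug / mean DMSO) per species; NaN where a group mean is 0."""
    drug_cols = [s for s, g in design.items() if g == drug_group]
    ctrl_cols = [s for s, g in design.items() if g == control_group]
    if not drug_cols or not ctrl_cols:
        raise ValueError("both groups must have at least one replicate")
    mean_d = normalized[drug_cols].mean(axis=1)
    mean_c = normalized[ctrl_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        resp = np.log2(mean_d / mean_c)
    resp[(mean_d <= 0) | (mean_c <= 0)] = np.nan
    resp.name = "log2_response"
    return resp


def kruskal_wallis(
    groups: list[np.ndarray] | list[list[float]], *, exact: str = "auto"
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its P-value.

    ``exact``: ``"never"`` uses the chi-square approximation; ``"always"``
    enumerates all label permutations; ``"auto"`` enumerates when total N <= 8.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    n_total = sum(a.size for a in arrays)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p_chi2 = stats.kruskal(*arrays)
    h = float(h)

    use_exact = exact == "always" or (exact == "auto" and n_total <= 8)
    if not use_exact:
        return h, float(p_chi2)
    return h, _kw_exact_p(arrays, h)


def _kw_h_from_ranks(ranks: np.ndarray, sizes: list[int], tie_term: float, n: int) -> float:
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start : start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _kw_exact_p(arrays: list[np.ndarray], h_obs: float) -> float:
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    sizes = [a.size for a in arrays]
    count_ge = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        h = _kw_h_from_ranks(ranks[list(perm)], sizes, tie_term, n)
        if h >= h_obs - 1e-9:
            count_ge += 1
        total += 1
    return count_ge / total


def differential_abundance(
    intensities: pd.DataFrame,
    standards: pd.DataFrame,
    design: dict[str, str],
    *,
    drug_group: str = "drug",
    control_group: str = "DMSO",
    alpha: float = 0.05,
    exact: str = "never",
) -> pd.DataFrame:
    """Full per-species chain: standard normalization, log2 response, KW test."""
    normed = normalize_to_standards(intensities, standards)
    resp = lipid_log2_response(
        normed, design, drug_group=drug_group, control_group=control_group
    )
    drug_cols = [s for s, g in design.items() if g == drug_group]
    ctrl_cols = [s for s, g in design.items() if g == control_group]
    rows = []
    for name in normed.index:
        h, p = kruskal_wallis(
            [normed.loc[name, drug_cols].to_numpy(), normed.loc[name, ctrl_cols].to_numpy()],
            exact=exact,
        )
        rows.append((name, resp[name], h, p, p < alpha))
    return pd.DataFrame(
        rows, columns=["species", "log2_response", "H", "p_value", "significant"]
    ).set_index("species")


@dataclass(frozen=True)
class ChainClass:
    length: str  # "short" | "long"
    saturated: bool


def classify_chain(species: LipidSpecies, cutoff: int = 32) -> ChainClass:
    """Short iff total acyl carbons <= cutoff (default 32 = C16+C16)."""
    return ChainClass(
        length="short" if species.carbons <= cutoff else "long",
        saturated=species.double_bonds == 0,
    )


# ---------------------------------------------------------------------------
# qPCR: 2^-ddCt
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct: pd.DataFrame,
    *,
    reference_gene: str = "ACT1",
    calibrator_condition: str = "DMSO",
) -> pd.DataFrame:
    """Fold changes per gene x condition by the 2^-ddCt method.

    ``ct`` needs columns ``gene``, ``sample``, ``condition``, ``ct``.  The
    reference gene must be measured in every sample; its dCt is 0 and its
    fold 1 by construction.
    """
    required = {"gene", "sample", "condition", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    missing = set(ct["sample"]) - set(ref.index)
    if missing:
        raise ValueError(f"reference gene {reference_gene} missing in samples {sorted(missing)}")

    work = ct.copy()
    work["dct"] = work["ct"] - work["sample"].map(ref).to_numpy()
    mean_dct = work.groupby(["gene", "condition"])["dct"].mean().unstack("condition")
    if calibrator_condition not in mean_dct.columns:
        raise ValueError(f"no samples for calibrator condition {calibrator_condition}")
    ddct = mean_dct.sub(mean_dct[calibrator_condition], axis=0)
    fold = 2.0 ** (-ddct)
    fold.columns.name = "condition"
    return fold


def delta_ct(
    ct: pd.DataFrame, *, reference_gene: str = "ACT1"
) -> pd.DataFrame:
    """Per-sample dCt table (gene, sample, condition, dct) for testing."""
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    work = ct[ct["gene"] != reference_gene].copy()
    work["dct"] = work["ct"] - work["sample"].map(ref).to_numpy()
    return work


def qpcr_test(
    values_a: np.ndarray | list[float],
    values_b: np.ndarray | list[float],
    *,
    paired: bool,
) -> tuple[float, float, bool]:
    """Two-sided t-test on dCt values; returns (t, p, degenerate_flag).

    Paired contrasts with zero-variance differences are degenerate: identical
    vectors give (0, 1); an exact constant shift gives p = 0 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.size != b.size or a.size < 2:
            raise ValueError("paired test needs equal-length vectors of size >= 2")
        diffs = a - b
        if np.allclose(diffs, diffs[0]):
            if np.allclose(diffs, 0):
                return 0.0, 1.0, True
            warnings.warn(
                "zero-variance paired differences with non-zero mean; p below machine epsilon",
                RuntimeWarning,
                stacklevel=2,
            )
            return math.copysign(math.inf, diffs[0]), 0.0, True
        res = stats.ttest_rel(a, b)
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("unpaired test needs >= 2 values per group")
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue), False
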