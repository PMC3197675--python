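"""Chemical-genetic interaction calling, SGA epsilon scores, MDR filtering and
hypergeometric category enrichment.

A chemical-genetic interaction is called by contrasting a double-deletion pool
(query deletion x genome-wide deletions, grown under drug) against the
corresponding single-deletion control pool: a gene is an aggravating
(negative) interactor when its double mutant is drug-sensitive, and the
interaction is query-dependent when the single mutant shows no significant
sensitivity of its own (tested at alpha = 0.025).  Alleviating (positive)
interactors are drug-resistant in the double pool.

Quantitative SGA interactions use the multiplicative neutral model: for
single-mutant fitnesses W_a, W_b and double-mutant fitness W_ab the
interaction score is epsilon = W_ab - W_a * W_b, called positive above +0.08
and negative below -0.08.

Category enrichment uses the upper-tail hypergeometric probability
P(X >= x) for drawing x category members in a hit list of size n from N genes
of which M belong to the category, Bonferroni-corrected across categories.
Multidrug-resistance (MDR) genes — those with fitness defects in at least a
given fraction (default 20%) of assayed stress conditions — can be filtered
out beforehand to isolate condition-specific hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .barcode_fitness import NONE, RESISTANT, SENSITIVE, FitnessTable, classify_fitness

logger = logging.getLogger(__name__)

AGGRAVATING = "aggravating"
ALLEVIATING = "alleviating"

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class InteractionCall:
    gene: str
    double_score: float
    double_p: float
    single_score: float
    single_p: float
    interaction_class: str  # aggravating | alleviating | none
    crg1_dependent: bool


def call_chemical_interactions(
    double_table: FitnessTable,
    single_table: FitnessTable,
    *,
    single_alpha: float = 0.025,
    score_threshold: float = 1.0,
) -> pd.DataFrame:
    """Join double- and single-pool fitness tables and call interactions.

    Class comes from the double pool (sensitive -> aggravating, resistant ->
    alleviating); the query-dependence flag additionally requires the single
    mutant to be uncalled at the stricter ``single_alpha``.  Genes present in
    only one table are flagged (``in_both`` False) and not called.
    """
    d = double_table.records.set_index("strain_id")
    s = single_table.records.set_index("strain_id")
    common = d.index.intersection(s.index)
    if len(common) == 0:
        raise ValueError("no genes shared between double and single pool tables")

    rows = []
    for gene in d.index.union(s.index):
        in_both = gene in common
        ds = d.loc[gene] if gene in d.index else None
        ss = s.loc[gene] if gene in s.index else None
        if not in_both:
            rows.append(
                (gene, getattr(ds, "score", float("nan")), getattr(ds, "p_value", float("nan")),
                 getattr(ss, "score", float("nan")), getattr(ss, "p_value", float("nan")),
                 NONE, False, False)
            )
            continue
        if ds["call"] == SENSITIVE:
            icls = AGGRAVATING
        elif ds["call"] == RESISTANT:
            icls = ALLEVIATING
        else:
            icls = NONE
        single_call = classify_fitness(
            ss["score"], ss["p_value"], score_threshold=score_threshold, alpha=single_alpha
        )
        dependent = icls != NONE and single_call == NONE
        rows.append(
            (gene, ds["score"], ds["p_value"], ss["score"], ss["p_value"], icls, dependent, True)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "double_score", "double_p", "single_score", "single_p",
            "interaction_class", "crg1_dependent", "in_both",
        ],
    ).set_index("gene")


@dataclass
class SgaRecord:
    gene: str
    w_a: float
    w_b: float
    w_ab: float
    epsilon: float
    interaction_class: str  # positive | negative | none


def sga_epsilon(
    w_a: float,
    w_b: float,
    w_ab: float,
    *,
    gene: str = "",
    threshold: float = 0.08,
    significant: bool = True,
) -> SgaRecord:
    """epsilon = W_ab - W_a*W_b under the multiplicative neutral model.

    Positive/alleviating above +threshold, negative/aggravating below
    -threshold, provided the interaction is significant.
    """
    if w_a < 0 or w_b < 0 or w_ab < 0:
        raise ValueError("fitness values must be non-negative")
    eps = w_ab - w_a * w_b
    if significant and eps > threshold:
        icls = POSITIVE
    elif significant and eps < -threshold:
        icls = NEGATIVE
    else:
        icls = NONE
    return SgaRecord(gene=gene, w_a=w_a, w_b=w_b, w_ab=w_ab, epsilon=eps, interaction_class=icls)


def sga_consensus(records_by_screen: list[list[SgaRecord]]) -> list[SgaRecord]:
    """Keep interactions whose non-none class agrees across replicate screens."""
    if not records_by_screen:
        return []
    by_gene = [
        {r.gene: r for r in screen} for screen in records_by_screen
    ]
    common = set.intersection(*(set(m) for m in by_gene))
    out = []
    for gene in sorted(common):
        classes = {m[gene].interaction_class for m in by_gene}
        if len(classes) == 1 and classes != {NONE}:
            out.append(by_gene[0][gene])
    return out


def filter_mdr(
    genes: list[str],
    catalog: pd.Series,
    threshold: float = 0.20,
) -> tuple[list[str], list[str]]:
    """Split genes into (retained, removed) by MDR condition fraction.

    ``catalog`` maps gene -> fraction of tested stress conditions with a
    fitness defect; genes at or above the threshold ("at least 20%") are
    removed.  Genes absent from the catalog are retained and logged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    retained, removed = [], []
    n_missing = 0
    for gene in genes:
        if gene not in catalog.index:
            n_missing += 1
            retained.append(gene)
        elif catalog[gene] >= threshold:
            removed.append(gene)
        else:
            retained.append(gene)
    if n_missing:
        logger.warning("%d genes absent from MDR catalog were retained", n_missing)
    return retained, removed


@dataclass(frozen=True)
class EnrichmentQuery:
    """x hits of a category of size M in a list of n genes from a universe of N."""

    x: int
    M: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError("require M <= N and n <= N")
        if self.x < 0:
            raise ValueError("x must be non-negative")


def hypergeom_pvalue(query: EnrichmentQuery) -> float:
    """Upper-tail P(X >= x), X ~ Hypergeometric(N, M, n), in log-space.

    x greater than min(M, n) is impossible and returns 0 by convention.
    """
    if query.x > min(query.M, query.n):
        return 0.0
    if query.x == 0:
        return 1.0
    return float(stats.hypergeom.sf(query.x - 1, query.N, query.M, query.n))


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """min(1, p * m) for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p_raw * m)


@dataclass
class EnrichmentResult:
    category: str
    query: EnrichmentQuery
    p_raw: float
    p_corrected: float
    significant: bool


def enrich_categories(
    hits: set[str] | list[str],
    universe: set[str] | list[str],
    annotation: dict[str, set[str] | list[str]],
    *,
    alpha: float = 0.01,
    correct_by: str = "categories",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every annotation category with >= 1 hit.

    ``annotation`` maps category -> member genes.  Unannotated genes count
    only toward N.  ``correct_by`` selects the Bonferroni multiplier:
    ``"categories"`` (standard) or ``"genes"`` (the number of genes in the
    hit list).  Results are sorted by corrected P; significance is judged on
    the raw P at ``alpha``.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if not hits:
        return []
    N, n = len(universe), len(hits)
    tested = []
    for category, members in annotation.items():
        members = set(members) & universe
        x = len(hits & members)
        if x == 0:
            continue
        q = EnrichmentQuery(x=x, M=len(members), n=n, N=N)
        tested.append((category, q, hypergeom_pvalue(q)))
    m = len(tested) if correct_by == "categories" else n
    results = [
        EnrichmentResult(
            category=cat,
            query=q,
            p_raw=p,
            p_corrected=bonferroni_adjust(p, max(m, 1)),
            significant=p < alpha,
        )
        for cat, q, p in tested
    ]
    results.sort(key=lambda r: (r.p_corrected, r.category))
    return results


def read_mdr_catalog(path) -> pd.Series:
    """Read a two-column TSV (gene, fraction) into a Series."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT-like annotation file: category <tab> description <tab> genes..."""
    annotation: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            annotation[parts[0]] = set(g for g in parts[2:] if g)
    return annotation
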