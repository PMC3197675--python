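"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec (seed included) and returns the
ground truth alongside the simulated data so downstream stages can be tested
by parameter recovery:

* pooled-barcode growth: per-tag intensities I = baseline * 2^(f*g) * 2^eps,
  eps ~ N(0, sigma) in log2 units, g = 1 on drug arrays — the multiplicative
  noise model matching the ratio statistics applied downstream;
* tiling arrays: probes evenly placed inside each ORF, probe log2 intensity =
  ORF expression + fixed per-probe affinity effect + array noise, plus the
  matching GFF3 text;
* lipidome: log-normal replicate intensities around group means, class-wise
  internal standards with the same coefficient of variation;
* qPCR Ct values with per-sample offsets (cancelled by dCt) and technical
  noise;
* LC-MS peak lists with Gaussian elution profiles, ppm-scale mass error, and
  component-dependent species presence across complete/omission reactions.

The default noise magnitudes are choices for test power (no platform noise
levels are prescribed by the assays themselves): pool sigma 0.25 log2 units,
tiling probe effect 0.25 / array noise 0.1, lipid CV 0.2, Ct SD 0.15,
mass error 30 ppm, retention-time jitter 0.05 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode_fitness import IntensityMatrix
from .lipidqpcr import LipidSpecies
from .msdetect import IonSpecies

# ---------------------------------------------------------------------------
# Pooled barcode fitness experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolSimSpec:
    """Spec for a pooled competitive-growth barcode experiment."""

    true_fitness: Mapping[str, float]
    n_replicates_drug: int = 3
    n_replicates_control: int = 3
    baseline_intensity: float = 1000.0
    baseline_spread_log2: float = 1.0
    noise_sd_log2: float = 0.25
    tags_per_strain: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates_drug < 1 or self.n_replicates_control < 1:
            raise ValueError("need at least one replicate per condition")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline intensity must be positive")
        if self.tags_per_strain < 1:
            raise ValueError("tags_per_strain must be >= 1")
        if not self.true_fitness:
            raise ValueError("true_fitness must name at least one strain")

    @property
    def strains(self) -> list[str]:
        return list(self.true_fitness)


def pool_spec_with_effects(
    n_strains: int,
    n_affected: int,
    effect: float,
    **kwargs,
) -> PoolSimSpec:
    """Convenience spec: first ``n_affected`` of ``n_strains`` carry ``effect``."""
    width = len(str(n_strains))
    fitness = {
        f"strain{i:0{width}d}": (effect if i < n_affected else 0.0)
        for i in range(n_strains)
    }
    return PoolSimSpec(true_fitness=fitness, **kwargs)


def simulate_pool_experiment(spec: PoolSimSpec) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Simulate tag intensities; returns (matrix, truth table).

    Truth table columns: ``strain_id``, ``true_f``.
    """
    rng = np.random.default_rng(spec.seed)
    strains = spec.strains
    tags, tag_strain = [], []
    for s in strains:
        for t in range(spec.tags_per_strain):
            tags.append(f"{s}_tag{t}")
            tag_strain.append(s)
    arrays = [f"drug_{r}" for r in range(spec.n_replicates_drug)] + [
        f"control_{r}" for r in range(spec.n_replicates_control)
    ]
    meta = pd.DataFrame(
        {
            "condition": ["drug"] * spec.n_replicates_drug
            + ["control"] * spec.n_replicates_control,
            "replicate": list(range(spec.n_replicates_drug))
            + list(range(spec.n_replicates_control)),
        },
        index=pd.Index(arrays, name="array_id"),
    )
    baselines = spec.baseline_intensity * 2.0 ** rng.normal(
        0.0, spec.baseline_spread_log2, size=len(tags)
    )
    f = np.array([spec.true_fitness[s] for s in tag_strain])
    g = np.array([1.0 if c == "drug" else 0.0 for c in meta["condition"]])
    noise = rng.normal(0.0, spec.noise_sd_log2, size=(len(tags), len(arrays)))
    values = baselines[:, None] * 2.0 ** (np.outer(f, g) + noise)
    matrix = IntensityMatrix(
        values=pd.DataFrame(values, index=pd.Index(tags, name="tag_id"), columns=arrays),
        tag_to_strain=pd.Series(tag_strain, index=tags),
        arrays=meta,
    )
    truth = pd.DataFrame(
        {"strain_id": strains, "true_f": [spec.true_fitness[s] for s in strains]}
    )
    return matrix, truth


def pool_long_table(matrix: IntensityMatrix) -> pd.DataFrame:
    """Long-format tag-intensity table (the on-disk TSV dialect)."""
    long = (
        matrix.values.rename_axis(index="tag_id", columns="array_id")
        .stack()
        .rename("intensity")
        .reset_index()
    )
    long["strain_id"] = long["tag_id"].map(matrix.tag_to_strain)
    long["condition"] = long["array_id"].map(matrix.arrays["condition"])
    long["replicate"] = long["array_id"].map(matrix.arrays["replicate"])
    return long[["tag_id", "strain_id", "array_id", "condition", "replicate", "intensity"]]


# ---------------------------------------------------------------------------
# Tiling arrays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TilingSimSpec:
    """Spec for a simulated tiling-array experiment.

    ``orfs``: (orf_id, chrom, start, end, strand) with 1-based inclusive
    coordinates; ``expr_log2`` maps orf_id -> {array_id: log2 expression};
    every ORF must map the same set of array ids.
    """

    orfs: Sequence[tuple[str, str, int, int, str]]
    expr_log2: Mapping[str, Mapping[str, float]]
    probes_per_orf: int = 5
    probe_length: int = 25
    probe_effect_sd: float = 0.25
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probes_per_orf < 1:
            raise ValueError("probes_per_orf must be >= 1")
        for orf_id, _c, start, end, _s in self.orfs:
            if start >= end:
                raise ValueError(f"ORF {orf_id}: start must be < end")
            if end - start + 1 < self.probe_length:
                raise ValueError(f"ORF {orf_id} shorter than one probe")
            if orf_id not in self.expr_log2:
                raise ValueError(f"no expression for ORF {orf_id}")

    @property
    def array_ids(self) -> list[str]:
        first = next(iter(self.expr_log2.values()))
        return list(first)


def simulate_tiling_arrays(
    spec: TilingSimSpec,
) -> tuple[pd.DataFrame, str, pd.DataFrame]:
    """Simulate a probe table and its GFF3; returns (probes, gff_text, truth).

    Probe starts are evenly spaced so every probe interval lies inside its
    source ORF.  Probe intensity = ORF log2 expression + per-probe affinity
    effect (shared across arrays) + per-measurement noise.
    """
    rng = np.random.default_rng(spec.seed)
    arrays = spec.array_ids
    rows = []
    truth_rows = []
    gff_lines = ["##gff-version 3"]
    for orf_id, chrom, start, end, strand in spec.orfs:
        gff_lines.append(
            "\t".join(
                [chrom, "crgpipe_sim", "gene", str(start), str(end), ".", strand, ".",
                 f"ID={orf_id}"]
            )
        )
        starts = np.linspace(start, end - spec.probe_length + 1, spec.probes_per_orf)
        starts = np.unique(np.round(starts).astype(int))
        effects = rng.normal(0.0, spec.probe_effect_sd, size=len(starts))
        for k, (pstart, eff) in enumerate(zip(starts, effects)):
            probe_id = f"{orf_id}_p{k}"
            row = {
                "probe_id": probe_id,
                "chrom": chrom,
                "start": int(pstart),
                "end": int(pstart) + spec.probe_length - 1,
                "strand": strand,
            }
            for a in arrays:
                noise = rng.normal(0.0, spec.noise_sd)
                row[a] = spec.expr_log2[orf_id][a] + eff + noise
            rows.append(row)
        for a in arrays:
            truth_rows.append((orf_id, a, spec.expr_log2[orf_id][a]))
    probes = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows, columns=["orf_id", "array_id", "expr_log2"])
    return probes, "\n".join(gff_lines) + "\n", truth


# ---------------------------------------------------------------------------
# Lipidome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LipidSimSpec:
    """Spec for a simulated internal-standard MRM lipidomics experiment.

    ``group_means`` maps species name -> {group: mean raw intensity};
    ``standard_intensity`` maps lipid class -> standard intensity.  Replicate
    intensities are log-normal around the group mean with coefficient of
    variation ``cv`` (sigma_ln = sqrt(ln(1 + cv^2))).
    """

    species: Sequence[LipidSpecies]
    group_means: Mapping[str, Mapping[str, float]]
    standard_intensity: Mapping[str, float]
    cv: float = 0.2
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for sp in self.species:
            if sp.lipid_class not in self.standard_intensity:
                raise ValueError(f"no internal standard for class {sp.lipid_class}")
            if sp.name not in self.group_means:
                raise ValueError(f"no group means for species {sp.name}")
            for group, mean in self.group_means[sp.name].items():
                if mean <= 0:
                    raise ValueError(f"non-positive mean for {sp.name} in {group}")

    @property
    def groups(self) -> list[str]:
        return list(next(iter(self.group_means.values())))


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma = np.sqrt(np.log1p(cv * cv))
    # mean-preserving log-normal: E[X] = mean
    return mean * np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=size))


def simulate_lipidome(
    spec: LipidSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate raw intensities and standards; returns (intensities, standards, truth).

    Samples are named ``{group}_{replicate}``; standards are per lipid class
    per sample with the same CV as the species intensities.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"{g}_{r}" for g in spec.groups for r in range(spec.n_replicates)]
    sample_group = {f"{g}_{r}": g for g in spec.groups for r in range(spec.n_replicates)}

    intensities = pd.DataFrame(
        index=pd.Index([sp.name for sp in spec.species], name="species"),
        columns=samples, dtype=float,
    )
    for sp in spec.species:
        for g in spec.groups:
            cols = [s for s in samples if sample_group[s] == g]
            intensities.loc[sp.name, cols] = _lognormal_around(
                rng, spec.group_means[sp.name][g], spec.cv, len(cols)
            )
    classes = sorted({sp.lipid_class for sp in spec.species})
    standards = pd.DataFrame(
        index=pd.Index(classes, name="lipid_class"), columns=samples, dtype=float
    )
    for cls in classes:
        standards.loc[cls] = _lognormal_around(
            rng, spec.standard_intensity[cls], spec.cv, len(samples)
        )
    truth = pd.DataFrame(
        [
            (sp.name, g, spec.group_means[sp.name][g],
             spec.group_means[sp.name][g] / spec.standard_intensity[sp.lipid_class])
            for sp in spec.species
            for g in spec.groups
        ],
        columns=["species", "group", "mean_intensity", "mean_normalized"],
    )
    return intensities, standards, truth


def lipid_design(spec: LipidSimSpec) -> dict[str, str]:
    """sample -> group map matching simulate_lipidome's sample naming."""
    return {
        f"{g}_{r}": g for g in spec.groups for r in range(spec.n_replicates)
    }


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrSimSpec:
    """Spec for simulated Ct tables.

    ``true_log2_fold`` maps (gene, condition) -> log2 fold change relative to
    the calibrator condition; the reference gene is unchanged everywhere.
    """

    genes: Sequence[str]
    conditions: Sequence[str]
    true_log2_fold: Mapping[tuple[str, str], float]
    reference_gene: str = "ACT1"
    calibrator_condition: str = "DMSO"
    base_ct: float = 22.0
    reference_ct: float = 16.0
    sample_offset_sd: float = 0.5
    ct_sd: float = 0.15
    n_replicates: int = 3
    seed: int = 0


def simulate_qpcr(spec: QpcrSimSpec) -> pd.DataFrame:
    """Simulate a long Ct table (gene, sample, condition, ct).

    A 1-unit increase in expression halves Ct: Ct = base - log2 fold + sample
    offset + noise; the per-sample offset models loading differences and is
    shared by the reference gene, so dCt cancels it.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond in spec.conditions:
        for rep in range(spec.n_replicates):
            sample = f"{cond}_{rep}"
            offset = rng.normal(0.0, spec.sample_offset_sd)
            rows.append(
                (spec.reference_gene, sample, cond,
                 spec.reference_ct + offset + rng.normal(0.0, spec.ct_sd))
            )
            for gene in spec.genes:
                if gene == spec.reference_gene:
                    continue
                fold = spec.true_log2_fold.get((gene, cond), 0.0)
                ct = spec.base_ct - fold + offset + rng.normal(0.0, spec.ct_sd)
                rows.append((gene, sample, cond, ct))
    return pd.DataFrame(rows, columns=["gene", "sample", "condition", "ct"])


# ---------------------------------------------------------------------------
# LC-MS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesPeak:
    """One simulated chromatographic species: where and when it appears."""

    species: IonSpecies
    rt_min: float
    intensity: float
    requires: frozenset[str]

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")


@dataclass(frozen=True)
class LcmsSimSpec:
    """Spec for simulated per-reaction LC-MS peak lists.

    ``reactions`` maps reaction id -> set of components present (for the
    enzymatic assay: enzyme, substrate, SAM).  A species appears in a
    reaction iff its ``requires`` set is a subset of the components present.
    """

    reactions: Mapping[str, frozenset[str]]
    species_peaks: Sequence[SpeciesPeak]
    mass_error_ppm_sd: float = 30.0
    rt_sd: float = 0.05
    peak_width_min: float = 0.1
    scan_interval: float = 0.05
    max_rt: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_error_ppm_sd < 0:
            raise ValueError("mass_error_ppm_sd must be >= 0")
        if self.rt_sd < 0 or self.peak_width_min <= 0 or self.scan_interval <= 0:
            raise ValueError("invalid chromatographic parameters")


def simulate_lcms(spec: LcmsSimSpec) -> dict[str, pd.DataFrame]:
    """Simulate peak lists; returns reaction id -> (rt_min, mz, intensity) frame.

    Each species present in a reaction elutes as a Gaussian profile around a
    jittered retention time; every scan-level centroid carries its own
    relative mass error of SD ``mass_error_ppm_sd`` ppm.
    """
    rng = np.random.default_rng(spec.seed)
    max_rt = spec.max_rt or (max(p.rt_min for p in spec.species_peaks) + 2.0)
    grid = np.arange(0.0, max_rt + spec.scan_interval, spec.scan_interval)
    out: dict[str, pd.DataFrame] = {}
    for rid in spec.reactions:
        components = spec.reactions[rid]
        rows = []
        for peak in spec.species_peaks:
            if not peak.requires <= components:
                continue
            rt_center = peak.rt_min + rng.normal(0.0, spec.rt_sd)
            profile = peak.intensity * np.exp(
                -0.5 * ((grid - rt_center) / spec.peak_width_min) ** 2
            )
            theo = peak.species.mz
            keep = profile > peak.intensity * 1e-4
            errors = rng.normal(0.0, spec.mass_error_ppm_sd, size=keep.sum())
            mz = theo * (1.0 + errors * 1e-6)
            for t, inten, m in zip(grid[keep], profile[keep], mz):
                rows.append((float(t), float(m), float(inten)))
        out[rid] = pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
    return out


def lcms_peak_table(peaks_by_reaction: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-reaction peak lists into the on-disk CSV layout."""
    frames = []
    for rid, df in peaks_by_reaction.items():
        if df.empty:
            continue  # reactions where nothing elutes contribute no rows
        frame = df.copy()
        frame.insert(0, "reaction_id", rid)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["reaction_id", "rt_min", "mz", "intensity"])
    return pd.concat(frames, ignore_index=True)
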