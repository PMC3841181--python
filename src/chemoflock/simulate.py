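"""Synthetic LC/MS cohorts with controlled chemo-genetic structure.

Each chemotype is a suite of compounds; each compound elutes as a
Gaussian peak at its retention-time center and deposits intensity on a
small set of nominal fragment masses in the 200-500 m/z analysis
window. An individual's signal is the chemotype's compound suite scaled
by a per-individual lognormal abundance factor (whole-extract
concentration varies between animals) with smaller per-compound
lognormal jitter, plus a linearly drifting baseline and truncated
Gaussian detector noise. Genetic labels (mitochondrial phylogroup and
optionally nuclear cluster) are attached per individual through the
design's ``genetic_map``, which lets presets realize the structures the
concordance analysis must distinguish: one-to-one concordance,
convergent chemistry across distant phylogroups, nuclear clusters
lumping several phylogroups, and one phylogroup split across
chemotypes.

At a scan time t, the intensity contributed by compound c on fragment
f is::

    g_i * j_{i,c} * proportion(c) * base_abundance(c) * rel(f)
        * exp(-(t - rt_center)^2 / (2 rt_sigma^2))

with g_i the individual's global lognormal factor (mean 1, CV
``abundance_cv``) and j the per-compound jitter (mean 1, CV
``compound_cv``). The Gaussian is the unnormalized kernel, so
``base_abundance`` is the apex intensity of a unit-proportion compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .msio import MassSpecRun, Scan, write_run


class DesignError(ValueError):
    pass


# fractional offset added to nominal fragment masses so that the
# downstream floor() binning is exercised, not just identity on integers
_MZ_OFFSET = 0.3

_MZ_WINDOW = (200, 500)


@dataclass(frozen=True)
class CompoundSpec:
    """One compound: Gaussian elution peak plus nominal fragment pattern."""

    compound_id: str
    rt_center: float                 # minutes
    rt_sigma: float                  # minutes
    fragment_pattern: tuple[tuple[int, float], ...]  # (nominal m/z, rel in (0,1])
    base_abundance: float = 100.0

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0:
            raise DesignError(f"{self.compound_id}: rt_sigma must be > 0")
        if not self.fragment_pattern:
            raise DesignError(f"{self.compound_id}: needs at least one fragment")
        rels = [r for _, r in self.fragment_pattern]
        for mz, rel in self.fragment_pattern:
            if not (_MZ_WINDOW[0] <= mz < _MZ_WINDOW[1]):
                raise DesignError(
                    f"{self.compound_id}: fragment m/z {mz} outside "
                    f"analysis window {_MZ_WINDOW}"
                )
            if not (0 < rel <= 1):
                raise DesignError(
                    f"{self.compound_id}: relative intensity {rel} outside (0, 1]"
                )
        if abs(max(rels) - 1.0) > 1e-9:
            raise DesignError(
                f"{self.compound_id}: fragment pattern must be normalized to max 1"
            )
        if self.base_abundance <= 0:
            raise DesignError(f"{self.compound_id}: base_abundance must be > 0")


@dataclass(frozen=True)
class ChemotypeSpec:
    """A compound suite with relative abundance weights."""

    chemotype_id: str
    compounds: tuple[CompoundSpec, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.compounds:
            raise DesignError(f"{self.chemotype_id}: needs at least one compound")
        if len(self.proportions) != len(self.compounds):
            raise DesignError(
                f"{self.chemotype_id}: {len(self.proportions)} proportions for "
                f"{len(self.compounds)} compounds"
            )
        if any(p <= 0 for p in self.proportions):
            raise DesignError(f"{self.chemotype_id}: proportions must be > 0")


@dataclass(frozen=True)
class CohortDesign:
    chemotypes: tuple[ChemotypeSpec, ...]
    n_per_chemotype: int = 6
    abundance_cv: float = 0.15       # per-individual global lognormal CV
    compound_cv: float = 0.05        # per-compound lognormal jitter CV
    baseline_level: float = 2.0      # intensity
    baseline_drift: float = 0.0      # intensity per minute
    noise_sd: float = 0.0            # additive detector noise
    rt_window: tuple[float, float] = (0.0, 17.0)
    scan_interval: float = 0.05      # minutes
    genetic_map: dict = field(default_factory=dict)  # chemotype -> PG | [PGs]
    nuclear_map: dict | None = None  # PG -> nuclear-cluster label
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [c.chemotype_id for c in self.chemotypes]
        if len(set(ids)) != len(ids):
            raise DesignError(f"duplicated chemotype ids: {ids}")
        if self.n_per_chemotype < 1:
            raise DesignError("n_per_chemotype must be >= 1")
        if self.noise_sd < 0 or self.abundance_cv < 0 or self.compound_cv < 0:
            raise DesignError("noise and CV parameters must be >= 0")
        if self.rt_window[0] >= self.rt_window[1]:
            raise DesignError(f"rt_window {self.rt_window} must have start < end")
        if self.scan_interval <= 0:
            raise DesignError("scan_interval must be > 0")
        missing = [i for i in ids if i not in self.genetic_map]
        if self.genetic_map and missing:
            raise DesignError(f"genetic_map missing chemotypes: {missing}")


@dataclass
class SimulatedCohort:
    runs: list[MassSpecRun]
    truth_chemotype: dict[str, str]
    truth_phylogroup: dict[str, str]
    truth_nuclear: dict[str, str] | None
    design: CohortDesign

    def __post_init__(self) -> None:
        ids = {r.individual_id for r in self.runs}
        if ids != set(self.truth_chemotype) or ids != set(self.truth_phylogroup):
            raise DesignError("truth tables do not cover every individual")


def scan_grid(design: CohortDesign) -> np.ndarray:
    start, end = design.rt_window
    n = int(np.floor((end - start) / design.scan_interval)) + 1
    grid = start + design.scan_interval * np.arange(n)
    if grid.size == 0:
        raise DesignError("empty scan grid")
    return grid


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Lognormal with mean exactly 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_run(individual_id: str, chemotype: ChemotypeSpec,
                 design: CohortDesign, rng: np.random.Generator) -> MassSpecRun:
    """Simulate one individual's acquisition on the design's scan grid.

    Identical inputs and generator state give bitwise-identical runs.
    Intensities are always finite and >= 0 (noise is truncated at zero).
    """
    grid = scan_grid(design)
    g = float(_lognormal_factor(rng, design.abundance_cv))
    jitter = _lognormal_factor(rng, design.compound_cv, size=len(chemotype.compounds))

    # the acquisition records the whole unit-mass window, so baseline and
    # detector noise appear on every channel, not just where this
    # chemotype's compounds fragment
    channels = list(range(*_MZ_WINDOW))
    chan_index = {mz: i for i, mz in enumerate(channels)}
    signal = np.zeros((len(channels), grid.size))
    for (compound, prop, jit) in zip(chemotype.compounds, chemotype.proportions,
                                     jitter):
        peak = np.exp(-((grid - compound.rt_center) ** 2)
                      / (2.0 * compound.rt_sigma ** 2))
        amp = g * float(jit) * prop * compound.base_abundance
        for mz, rel in compound.fragment_pattern:
            signal[chan_index[mz]] += amp * rel * peak
    signal += design.baseline_level + design.baseline_drift * grid[None, :]
    if design.noise_sd > 0:
        signal += rng.normal(0.0, design.noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, None)

    mz_values = np.array(channels, dtype=float) + _MZ_OFFSET
    scans = [
        Scan(rt=float(t), mz=mz_values.copy(), intensity=signal[:, j].copy())
        for j, t in enumerate(grid)
    ]
    return MassSpecRun(individual_id=individual_id, scans=scans)


def _phylogroups_for(design: CohortDesign, chemotype_id: str) -> list[str]:
    value = design.genetic_map.get(chemotype_id, chemotype_id)
    if isinstance(value, str):
        return [value]
    return list(value)


def simulate_cohort(design: CohortDesign) -> SimulatedCohort:
    """Simulate ``n_per_chemotype`` individuals per chemotype.

    Per-individual random streams are spawned from the design seed, so
    the cohort is reproducible regardless of how it is later consumed.
    When a chemotype maps to several phylogroups, its individuals are
    assigned to them round-robin.
    """
    root = np.random.SeedSequence(design.seed)
    children = root.spawn(len(design.chemotypes) * design.n_per_chemotype)
    runs: list[MassSpecRun] = []
    truth_ct: dict[str, str] = {}
    truth_pg: dict[str, str] = {}
    truth_nc: dict[str, str] = {}
    k = 0
    for chemotype in design.chemotypes:
        pgs = _phylogroups_for(design, chemotype.chemotype_id)
        for i in range(design.n_per_chemotype):
            ind = f"{chemotype.chemotype_id}_{i + 1:02d}"
            rng = np.random.default_rng(children[k])
            k += 1
            runs.append(simulate_run(ind, chemotype, design, rng))
            truth_ct[ind] = chemotype.chemotype_id
            pg = pgs[i % len(pgs)]
            truth_pg[ind] = pg
            if design.nuclear_map is not None:
                truth_nc[ind] = design.nuclear_map.get(pg, pg)
    return SimulatedCohort(
        runs=runs, truth_chemotype=truth_ct, truth_phylogroup=truth_pg,
        truth_nuclear=truth_nc if design.nuclear_map is not None else None,
        design=design,
    )


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def _suite(prefix: str, fragment_sets: list[list[int]], rt_centers: list[float],
           base: float = 100.0) -> tuple[CompoundSpec, ...]:
    """Compounds with 3-fragment patterns (rel 1, 0.7, 0.4) at given RTs."""
    compounds = []
    for i, (frags, rt) in enumerate(zip(fragment_sets, rt_centers)):
        rels = (1.0, 0.7, 0.4)[: len(frags)]
        pattern = tuple(zip(frags, rels))
        compounds.append(CompoundSpec(
            compound_id=f"{prefix}_c{i + 1}", rt_center=rt, rt_sigma=0.25,
            fragment_pattern=pattern, base_abundance=base,
        ))
    return tuple(compounds)


def scenario_preset(name: str, seed: int = 0) -> CohortDesign:
    """Named cohort designs realizing the concordance structures.

    - ``concordant``: four chemotypes with disjoint compound suites,
      mapped one-to-one onto phylogroups; low noise. The pipeline must
      recover the truth partition exactly.
    - ``convergent_chemistry``: two phylogroups (PG24, PG29) share the
      same compound suite with different proportion vectors, so the
      correlation dendrogram merges them while PCA separates them; a
      third, disjoint chemotype (PG8) anchors the contrast.
    - ``lumped_nuclear``: four concordant phylogroups, but the nuclear
      marker lumps two of them under one cluster label.
    - ``split_phylogroup``: one phylogroup (PG29) spans two chemotypes
      whose fingerprints differ in shape (cross-correlation below the
      0.3 cut) while a large per-individual abundance spread makes
      their PCA clouds overlap — a chemical split the geometry does not
      corroborate.
    """
    if name == "concordant":
        chemotypes = tuple(
            ChemotypeSpec(
                chemotype_id=f"CT{k + 1}",
                compounds=_suite(
                    f"CT{k + 1}",
                    [[210 + 60 * k + 10 * j + d for d in (0, 2, 5)] for j in range(3)],
                    [4.0 + 1.5 * j + 0.4 * k for j in range(3)],
                ),
                proportions=(1.0, 0.6, 0.3),
            )
            for k in range(4)
        )
        return CohortDesign(
            chemotypes=chemotypes, n_per_chemotype=6,
            abundance_cv=0.15, compound_cv=0.05,
            baseline_level=2.0, baseline_drift=0.1, noise_sd=0.3,
            genetic_map={f"CT{k + 1}": f"PG{k + 1}" for k in range(4)},
            seed=seed,
        )

    if name == "convergent_chemistry":
        shared = _suite("SH", [[230, 233, 238], [300, 304, 309], [370, 373, 377]],
                        [4.5, 7.0, 10.0])
        other = _suite("OT", [[255, 258, 262], [330, 335, 338], [410, 414, 419]],
                       [5.0, 8.0, 11.0])
        chemotypes = (
            ChemotypeSpec("CT_A", shared, proportions=(1.0, 0.45, 0.15)),
            ChemotypeSpec("CT_B", shared, proportions=(0.15, 0.45, 1.0)),
            ChemotypeSpec("CT_C", other, proportions=(1.0, 0.6, 0.3)),
        )
        return CohortDesign(
            chemotypes=chemotypes, n_per_chemotype=6,
            abundance_cv=0.10, compound_cv=0.04,
            baseline_level=2.0, baseline_drift=0.1, noise_sd=0.3,
            genetic_map={"CT_A": "PG24", "CT_B": "PG29", "CT_C": "PG8"},
            seed=seed,
        )

    if name == "lumped_nuclear":
        design = scenario_preset("concordant", seed=seed)
        return CohortDesign(
            **{**asdict_shallow(design),
               "nuclear_map": {"PG1": "ANT1", "PG2": "ANT1",
                               "PG3": "ANT2", "PG4": "ANT3"}},
        )

    if name == "split_phylogroup":
        # PG29 spans two minor chemotypes S1/S2 whose suites differ in
        # shape (cross-correlation well below the 0.3 cut) but whose
        # absolute signal is small next to the dominant X/Y chemotypes.
        # PC1-2 are spanned by the X/Y directions, so in that plane the
        # S clouds sit near the origin and their scatter is the detector
        # noise floor: the chemical split is not corroborated by PCA,
        # which is the pattern this preset exists to produce.
        common = _suite("CM", [[240, 244, 249]], [6.0], base=25.0)
        own1 = _suite("S1", [[280, 283, 288], [350, 354, 359]], [5.0, 9.0],
                      base=50.0)
        own2 = _suite("S2", [[300, 303, 308], [430, 434, 439]], [5.5, 9.5],
                      base=50.0)
        xs = _suite("X", [[460, 464, 469], [210, 214, 219]], [4.0, 8.5],
                    base=3000.0)
        ys = _suite("Y", [[330, 334, 339], [390, 394, 399]], [4.8, 10.5],
                    base=3000.0)
        chemotypes = (
            ChemotypeSpec("CT_S1", common + own1, proportions=(1.0, 1.0, 0.7)),
            ChemotypeSpec("CT_S2", common + own2, proportions=(1.0, 1.0, 0.7)),
            ChemotypeSpec("CT_X", xs, proportions=(1.0, 0.6)),
            ChemotypeSpec("CT_Y", ys, proportions=(1.0, 0.6)),
        )
        return CohortDesign(
            chemotypes=chemotypes, n_per_chemotype=16,
            abundance_cv=0.3, compound_cv=0.10,
            baseline_level=2.0, baseline_drift=0.02, noise_sd=2.0,
            genetic_map={"CT_S1": "PG29", "CT_S2": "PG29",
                         "CT_X": "PG5", "CT_Y": "PG6"},
            seed=seed,
        )

    raise DesignError(
        f"unknown preset {name!r}; choose from concordant, convergent_chemistry, "
        f"lumped_nuclear, split_phylogroup"
    )


def asdict_shallow(design: CohortDesign) -> dict:
    """Design fields as a dict without recursing into the chemotype specs."""
    return {f: getattr(design, f) for f in design.__dataclass_fields__}


# ---------------------------------------------------------------------------
# optional sequence-level simulation (star phylogeny)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_gene_partition(truth_phylogroup: dict[str, str], gene: str,
                            length: int, rng: np.random.Generator,
                            divergence: float = 0.10,
                            within_rate: float = 0.005):
    """Star-phylogeny sequence sampler for one gene.

    A random root sequence diverges independently into each phylogroup
    (a fraction ``divergence`` of sites mutated per phylogroup), and
    each individual then accumulates a small number of private
    mutations (``within_rate``). Nuclear markers evolve more slowly
    than mitochondrial ones, so callers pass a smaller ``divergence``
    for them. Returns a dict id -> sequence usable as a
    ``GenePartition`` alignment.
    """
    root = rng.choice(_BASES, size=length)
    pg_seqs: dict[str, np.ndarray] = {}
    for pg in sorted(set(truth_phylogroup.values())):
        seq = root.copy()
        n_mut = int(round(divergence * length))
        sites = rng.choice(length, size=n_mut, replace=False)
        for s in sites:
            seq[s] = rng.choice(_BASES[_BASES != seq[s]])
        pg_seqs[pg] = seq
    alignment: dict[str, str] = {}
    for ind in sorted(truth_phylogroup):
        seq = pg_seqs[truth_phylogroup[ind]].copy()
        n_mut = rng.binomial(length, within_rate)
        if n_mut:
            sites = rng.choice(length, size=n_mut, replace=False)
            for s in sites:
                seq[s] = rng.choice(_BASES[_BASES != seq[s]])
        alignment[ind] = "".join(seq)
    return alignment


# ---------------------------------------------------------------------------
# cohort serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir: str | Path,
                 format: str = "scan_table") -> Path:
    """Write runs (one file per individual) plus a truth table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "mzML" if format == "mzml" else "tsv"
    for run in cohort.runs:
        write_run(run, outdir / f"{run.individual_id}.{ext}", format=format)
    return write_truth_tables(cohort, outdir)


def write_truth_tables(cohort: SimulatedCohort, outdir: str | Path) -> Path:
    """Write only the truth table and design, not the (large) run files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth.tsv", "w") as fh:
        cols = ["individual_id", "chemotype_id", "phylogroup"]
        if cohort.truth_nuclear is not None:
            cols.append("nuclear_cluster")
        fh.write("\t".join(cols) + "\n")
        for run in cohort.runs:
            ind = run.individual_id
            row = [ind, cohort.truth_chemotype[ind], cohort.truth_phylogroup[ind]]
            if cohort.truth_nuclear is not None:
                row.append(cohort.truth_nuclear[ind])
            fh.write("\t".join(row) + "\n")
    design = asdict(cohort.design)
    design["chemotypes"] = [asdict(c) for c in cohort.design.chemotypes]
    (outdir / "design.json").write_text(json.dumps(design, indent=1, sort_keys=True,
                                                   default=list))
    return outdir
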