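"""Seeded synthetic multi-omic data generator with a planted-truth ledger.

Emulates every input of the niche-mapping pipeline at desk scale:

* bulk RNA-seq counts for two myeloid diseases (bcCML, AML) against a shared
  healthy-control design, negative-binomial with planted upregulated receptor
  genes;
* a genome-wide CRISPR dropout screen as per-guide log2 fold-changes;
* stage- and population-labelled single-cell niche expression with planted
  ligand genes following one of four temporal classes (steady, lost,
  transient, population_shift) and drifting population proportions;
* a bipartite ligand-receptor interaction table with planted true axes,
  decoy pairs and deliberately ligand-less receptors;
* per-gene patient survival tables with exponential event times and an
  expression-dependent hazard;
* median-effect dose-response curves for two drugs.

Every generator is driven by one root seed; identical configs produce
byte-identical outputs. The ground truth of everything planted is recorded in
a :class:`TruthLedger` so downstream recovery can be scored mechanically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "TEMPORAL_CLASSES",
    "PlantedReceptor",
    "PlantedDropout",
    "PlantedLigand",
    "LRPair",
    "SurvivalSpec",
    "SynergySpec",
    "SynthConfig",
    "TruthLedger",
    "SynthData",
    "simulate_bulk",
    "simulate_screen",
    "simulate_niche",
    "simulate_survival",
    "simulate_lr_table",
    "simulate_synergy",
    "simulate_all",
    "default_config",
]

STAGES = ("naive", "initiation", "expansion", "end")
TEMPORAL_CLASSES = ("steady", "lost", "transient", "population_shift")

# fixed per-dataset stream ids so each generator draws from an independent,
# reproducible substream of the root seed
_STREAM = {
    "bulk_bcCML": 1,
    "bulk_AML": 2,
    "screen": 3,
    "niche": 4,
    "survival": 5,
    "lr": 6,
    "synergy": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


@dataclass(frozen=True)
class PlantedReceptor:
    gene: str
    disease: str  # "bcCML" | "AML" | "both"
    log2fc: float


@dataclass(frozen=True)
class PlantedDropout:
    gene: str
    log2fc: float  # mean per-guide effect, must be <= -1


@dataclass(frozen=True)
class PlantedLigand:
    gene: str
    populations: tuple  # one population; two for population_shift
    temporal_class: str


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    planted: bool


@dataclass(frozen=True)
class SurvivalSpec:
    genes: tuple
    betas: dict  # gene -> log-hazard per unit expression (missing = 0)
    n_patients: int = 161
    baseline_hazard: float = 0.1
    censor_time: float = 30.0
    expr_mean: float = 10.0
    expr_sd: float = 2.0


@dataclass(frozen=True)
class SynergySpec:
    m1: float = 2.0
    dm1: float = 1.0
    m2: float = 1.5
    dm2: float = 10.0
    doses1: tuple = (0.25, 0.5, 1.0, 2.0, 4.0)
    doses2: tuple = (2.5, 5.0, 10.0, 20.0, 40.0)
    noise_sd: float = 0.0  # gaussian noise on the linearized response


@dataclass
class SynthConfig:
    """Full configuration of the synthetic study.

    The defaults (see :func:`default_config`) define the reference study
    conditions: a 500-gene bulk universe with six planted receptors shared
    between or unique to the two diseases, a screen in which planted
    receptors and decoys drop out, a four-population niche over the four
    disease stages with eight planted ligands covering all temporal classes,
    a 22-receptor survival panel with two prognostic genes, and two
    median-effect drug curves.
    """

    seed: int = 1
    # bulk
    n_genes: int = 500
    n_samples_per_group: int = 8
    nb_dispersion: float = 0.1
    baseline_mean_range: tuple = (1.0, 1000.0)  # log-uniform gene baselines
    planted_min_mean: float = 30.0  # planted receptors are expressed genes
    planted_receptors: list = field(default_factory=list)
    # screen
    n_guides_per_gene: int = 4
    guide_sd: float = 0.3
    dropout_genes: list = field(default_factory=list)
    # niche
    stages: tuple = STAGES
    populations: dict = field(default_factory=dict)  # name -> 4 proportions
    n_cells_per_stage: int = 300
    n_background_genes: int = 60
    ligand_mean: float = 3.0
    background_mean: float = 0.3
    offtarget_mean: float = 0.01
    lost_expansion_level: float | None = None  # None = full level at expansion
    shift_stage: int = 2  # stage index where population_shift switches
    planted_ligands: list = field(default_factory=list)
    # ligand-receptor table
    lr_pairs: list = field(default_factory=list)
    n_decoy_pairs: int = 10
    ligandless_receptors: list = field(default_factory=list)
    blacklist_genes: list = field(default_factory=list)
    # survival / synergy
    survival: SurvivalSpec | None = None
    synergy: SynergySpec = field(default_factory=SynergySpec)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_guides_per_gene < 1:
            raise ValueError("n_guides_per_gene must be >= 1")
        genes = self.bulk_genes()
        if len(genes) > self.n_genes:
            raise ValueError(
                f"gene universe of {self.n_genes} cannot hold "
                f"{len(genes)} named planted genes"
            )
        for pr in self.planted_receptors:
            if pr.disease not in ("bcCML", "AML", "both"):
                raise ValueError(f"unknown disease category {pr.disease!r}")
        for d in self.dropout_genes:
            if d.log2fc > -1:
                raise ValueError(
                    f"planted dropout {d.gene} effect {d.log2fc} must be <= -1"
                )
        if len(self.stages) != 4:
            raise ValueError("exactly four ordered stages are required")
        for pop, props in self.populations.items():
            props = np.asarray(props, float)
            if props.size != len(self.stages) or np.any(props < 0):
                raise ValueError(f"population {pop}: need one proportion per stage")
        if self.populations:
            totals = np.sum([list(v) for v in self.populations.values()], axis=0)
            if np.any(np.abs(totals - 1.0) > 1e-9):
                raise ValueError(
                    f"per-stage population proportions must sum to 1, got {totals}"
                )
        for pl in self.planted_ligands:
            if pl.temporal_class not in TEMPORAL_CLASSES:
                raise ValueError(f"unknown temporal class {pl.temporal_class!r}")
            need = 2 if pl.temporal_class == "population_shift" else 1
            if len(pl.populations) < need:
                raise ValueError(
                    f"ligand {pl.gene}: class {pl.temporal_class} needs "
                    f"{need} population(s)"
                )
            for pop in pl.populations:
                if pop not in self.populations:
                    raise ValueError(f"ligand {pl.gene}: unknown population {pop}")
        planted_receptor_names = {p.gene for p in self.planted_receptors}
        pair_ligands = {p.ligand for p in self.lr_pairs if p.planted}
        for pl in self.planted_ligands:
            if pl.gene not in pair_ligands:
                raise ValueError(
                    f"planted ligand {pl.gene} has no planted ligand-receptor pair"
                )
        pair_receptors = {p.receptor for p in self.lr_pairs}
        clash = set(self.ligandless_receptors) & pair_receptors
        if clash:
            raise ValueError(
                f"ligandless receptors appear in lr_pairs: {sorted(clash)}"
            )
        for p in self.lr_pairs:
            if p.planted and p.receptor not in planted_receptor_names:
                raise ValueError(
                    f"planted pair ({p.ligand}, {p.receptor}): receptor not planted"
                )

    # -- derived universes --------------------------------------------------
    def bulk_genes(self) -> list:
        """Bulk gene universe: named planted entities first, then fillers."""
        named = []
        seen = set()
        for g in (
            [p.gene for p in self.planted_receptors]
            + [d.gene for d in self.dropout_genes]
            + list(self.blacklist_genes)
            + list(self.ligandless_receptors)
            + [p.receptor for p in self.lr_pairs]
        ):
            if g not in seen:
                named.append(g)
                seen.add(g)
        fillers = []
        i = 1
        while len(named) + len(fillers) < self.n_genes:
            name = f"G{i:04d}"
            if name not in seen:
                fillers.append(name)
            i += 1
        return named + fillers

    def niche_genes(self) -> list:
        named = []
        seen = set()
        for g in [p.gene for p in self.planted_ligands] + [
            p.ligand for p in self.lr_pairs
        ]:
            if g not in seen:
                named.append(g)
                seen.add(g)
        background = [f"NG{i:03d}" for i in range(1, self.n_background_genes + 1)]
        return named + background


class TruthLedger:
    """Machine-readable record of everything planted, keyed per dataset."""

    def __init__(self):
        self.tables: dict = {}

    def record(self, dataset: str, payload) -> None:
        self.tables[dataset] = payload

    def to_json(self) -> str:
        return json.dumps(self.tables, indent=2, sort_keys=True, default=str)

    def __getitem__(self, key):
        return self.tables[key]


@dataclass
class SynthData:
    """Bundle of all generated inputs plus the truth ledger."""

    bulk: dict  # disease -> (counts DataFrame, groups array)
    screen: pd.DataFrame
    niche_counts: pd.DataFrame  # cells x genes
    niche_meta: pd.DataFrame  # cell_id, population, stage
    lr_table: pd.DataFrame
    survival: pd.DataFrame
    synergy: dict  # drug -> DataFrame(dose, fa)
    truth: TruthLedger


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _nb_sample(rng, mean, dispersion, size):
    """NB draw with Var = mu + phi mu^2 (shape r = 1/phi)."""
    r = 1.0 / dispersion
    mean = np.broadcast_to(mean, size)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_bulk(config: SynthConfig, truth: TruthLedger | None = None) -> dict:
    """Two-disease bulk counts with planted upregulated genes.

    Returns ``{"bcCML": (counts, groups), "AML": (counts, groups)}`` where
    counts is a gene x sample DataFrame and groups labels each sample
    ``control`` or ``disease``. Both diseases share the gene baseline design;
    planted genes have their disease-group mean multiplied by 2**log2fc.
    """
    config.validate()
    genes = config.bulk_genes()
    n = config.n_samples_per_group
    lo, hi = config.baseline_mean_range
    # baselines must be shared across diseases: draw from a dedicated stream
    base_rng = np.random.default_rng([int(config.seed), 0])
    base = np.exp(base_rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    effects = {"bcCML": np.zeros(len(genes)), "AML": np.zeros(len(genes))}
    gene_ix = {g: i for i, g in enumerate(genes)}
    # candidate surface receptors are expressed genes: floor their baseline
    for pr in config.planted_receptors:
        i = gene_ix[pr.gene]
        base[i] = max(base[i], config.planted_min_mean)
    for pr in config.planted_receptors:
        targets = ("bcCML", "AML") if pr.disease == "both" else (pr.disease,)
        for d in targets:
            effects[d][gene_ix[pr.gene]] = pr.log2fc
    out = {}
    for disease in ("bcCML", "AML"):
        rng = _rng(config.seed, f"bulk_{disease}")
        ctrl = _nb_sample(rng, base[:, None], config.nb_dispersion, (len(genes), n))
        dis_mean = base * 2.0 ** effects[disease]
        dis = _nb_sample(rng, dis_mean[:, None], config.nb_dispersion, (len(genes), n))
        counts = pd.DataFrame(
            np.hstack([ctrl, dis]),
            index=pd.Index(genes, name="gene"),
            columns=[f"{disease}_ctrl_{i+1}" for i in range(n)]
            + [f"{disease}_case_{i+1}" for i in range(n)],
        )
        groups = np.array(["control"] * n + ["disease"] * n)
        out[disease] = (counts, groups)
    if truth is not None:
        truth.record(
            "bulk",
            {
                "planted_receptors": [asdict(p) for p in config.planted_receptors],
                "n_genes": len(genes),
                "n_samples_per_group": n,
            },
        )
    return out


def simulate_screen(
    config: SynthConfig, truth: TruthLedger | None = None
) -> pd.DataFrame:
    """Per-guide CRISPR dropout screen table (gene, guide, log2fc)."""
    config.validate()
    genes = config.bulk_genes()
    rng = _rng(config.seed, "screen")
    effect = {d.gene: d.log2fc for d in config.dropout_genes}
    k = config.n_guides_per_gene
    eff = np.array([effect.get(g, 0.0) for g in genes])
    vals = rng.normal(eff[:, None], config.guide_sd, size=(len(genes), k))
    df = pd.DataFrame(
        {
            "gene": np.repeat(genes, k),
            "guide": [f"{g}_g{i+1}" for g in genes for i in range(k)],
            "log2fc": vals.ravel(),
        }
    )
    if truth is not None:
        truth.record(
            "screen", {"dropout_genes": [asdict(d) for d in config.dropout_genes]}
        )
    return df


def _ligand_stage_means(config: SynthConfig, ligand: PlantedLigand) -> dict:
    """Per-(population, stage) mean template for one planted ligand."""
    mu = config.ligand_mean
    off = config.offtarget_mean
    lost_mid = mu if config.lost_expansion_level is None else config.lost_expansion_level
    means = {
        (pop, s): off for pop in config.populations for s in range(len(config.stages))
    }
    cls = ligand.temporal_class
    if cls == "steady":
        for s in range(4):
            means[(ligand.populations[0], s)] = mu
    elif cls == "lost":
        tmpl = (mu, mu, lost_mid, off)
        for s in range(4):
            means[(ligand.populations[0], s)] = tmpl[s]
    elif cls == "transient":
        tmpl = (off, mu, mu, off)
        for s in range(4):
            means[(ligand.populations[0], s)] = tmpl[s]
    elif cls == "population_shift":
        pop_a, pop_b = ligand.populations[0], ligand.populations[1]
        for s in range(4):
            means[(pop_a if s < config.shift_stage else pop_b, s)] = mu
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(f"unknown temporal class {cls!r}")
    return means


def simulate_niche(config: SynthConfig, truth: TruthLedger | None = None):
    """Stage x population single-cell niche counts with planted ligands.

    Returns (counts cells x genes, metadata with cell_id/population/stage).
    Cells are assigned to populations multinomially per stage; counts are
    Poisson around population x stage gene means given by the temporal-class
    templates.
    """
    config.validate()
    if not config.populations:
        raise ValueError("no populations configured")
    rng = _rng(config.seed, "niche")
    pops = list(config.populations)
    genes = config.niche_genes()
    planted = {pl.gene: pl for pl in config.planted_ligands}

    # mean tensor gene x population x stage
    mean = np.full((len(genes), len(pops), 4), config.offtarget_mean)
    background = set(genes) - set(planted)
    for gi, g in enumerate(genes):
        if g in background:
            mean[gi, :, :] = config.background_mean
    pop_ix = {p: i for i, p in enumerate(pops)}
    for gi, g in enumerate(genes):
        if g in planted:
            for (pop, s), m in _ligand_stage_means(config, planted[g]).items():
                mean[gi, pop_ix[pop], s] = m

    # Depth padding: hold the expected per-cell total constant across
    # (population, stage) groups so that library-size normalization cannot
    # turn unplanted genes into spurious compositional markers.
    totals = mean.sum(axis=0)
    pad = totals.max() - totals
    genes = genes + ["DEPTH_PAD"]
    mean = np.concatenate([mean, pad[None, :, :]], axis=0)

    cells, rows = [], []
    for s, stage in enumerate(config.stages):
        props = np.array([config.populations[p][s] for p in pops], float)
        assign = rng.choice(len(pops), size=config.n_cells_per_stage, p=props)
        for ci, pi in enumerate(assign):
            cells.append(
                {
                    "cell_id": f"{stage}_c{ci+1:04d}",
                    "population": pops[pi],
                    "stage": stage,
                }
            )
            rows.append(rng.poisson(mean[:, pi, s]))
    meta = pd.DataFrame(cells).set_index("cell_id", drop=False)
    counts = pd.DataFrame(
        np.asarray(rows), index=meta.index, columns=pd.Index(genes, name="gene")
    )
    if truth is not None:
        truth.record(
            "niche",
            {
                "planted_ligands": [asdict(p) for p in config.planted_ligands],
                "population_proportions": {
                    p: list(map(float, config.populations[p])) for p in pops
                },
            },
        )
    return counts, meta


def simulate_survival(
    config: SynthConfig, truth: TruthLedger | None = None
) -> pd.DataFrame:
    """Per-gene patient survival tables in long form.

    Columns: gene, id, time, event, expression. Event times are exponential
    with rate h0 * exp(beta * (expression - expr_mean)); censoring is uniform
    on (0, censor_time).
    """
    spec = config.survival
    if spec is None:
        raise ValueError("config.survival is not set")
    if spec.censor_time <= 0:
        raise ValueError("censoring window must be positive")
    for g, b in spec.betas.items():
        if not np.isfinite(b):
            raise ValueError(f"beta for {g} must be finite")
    rng = _rng(config.seed, "survival")
    frames = []
    for gene in spec.genes:
        beta = spec.betas.get(gene, 0.0)
        expr = rng.normal(spec.expr_mean, spec.expr_sd, size=spec.n_patients)
        rate = spec.baseline_hazard * np.exp(beta * (expr - spec.expr_mean))
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.uniform(0.0, spec.censor_time, size=spec.n_patients)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "id": [f"{gene}_p{i+1:03d}" for i in range(spec.n_patients)],
                    "time": time,
                    "event": event,
                    "expression": expr,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if truth is not None:
        truth.record(
            "survival",
            {
                "betas": {g: float(b) for g, b in spec.betas.items()},
                "genes": list(spec.genes),
                "n_patients": spec.n_patients,
            },
        )
    return df


def simulate_lr_table(
    config: SynthConfig, truth: TruthLedger | None = None
) -> pd.DataFrame:
    """Ligand-receptor interaction table: planted pairs + random decoys.

    Decoy pairs join background niche genes to receptors drawn from the bulk
    universe (never a configured ligand-less receptor), so a decoy edge can
    only arise through a genuine false-positive enrichment call downstream.
    """
    config.validate()
    rng = _rng(config.seed, "lr")
    rows = [
        {"ligand": p.ligand, "receptor": p.receptor, "source": "planted" if p.planted else "curated"}
        for p in config.lr_pairs
    ]
    background = [f"NG{i:03d}" for i in range(1, config.n_background_genes + 1)]
    receptors = [
        g
        for g in config.bulk_genes()
        if g not in set(config.ligandless_receptors)
    ]
    existing = {(r["ligand"], r["receptor"]) for r in rows}
    n_made = 0
    while n_made < config.n_decoy_pairs:
        lig = background[rng.integers(len(background))]
        rec = receptors[rng.integers(len(receptors))]
        if (lig, rec) in existing:
            continue
        rows.append({"ligand": lig, "receptor": rec, "source": "decoy"})
        existing.add((lig, rec))
        n_made += 1
    df = pd.DataFrame(rows)
    if truth is not None:
        truth.record(
            "lr",
            {
                "planted_pairs": [
                    [p.ligand, p.receptor] for p in config.lr_pairs if p.planted
                ],
                "ligandless_receptors": list(config.ligandless_receptors),
            },
        )
    return df


def _median_effect_fa(dose, m, dm):
    """fa from the median-effect equation fa/(1-fa) = (D/Dm)^m."""
    ratio = (np.asarray(dose, float) / dm) ** m
    return ratio / (1.0 + ratio)


def simulate_synergy(config: SynthConfig, truth: TruthLedger | None = None) -> dict:
    """Dose-response tables for two drugs from planted median-effect curves."""
    spec = config.synergy
    rng = _rng(config.seed, "synergy")
    out = {}
    for name, m, dm, doses in (
        ("drug1", spec.m1, spec.dm1, spec.doses1),
        ("drug2", spec.m2, spec.dm2, spec.doses2),
    ):
        fa = _median_effect_fa(doses, m, dm)
        if spec.noise_sd > 0:
            y = np.log10(fa / (1 - fa)) + rng.normal(0, spec.noise_sd, len(fa))
            fa = 10.0 ** y / (1 + 10.0 ** y)
        out[name] = pd.DataFrame({"dose": doses, "fa": fa})
    if truth is not None:
        truth.record(
            "synergy",
            {"drug1": {"m": spec.m1, "dm": spec.dm1}, "drug2": {"m": spec.m2, "dm": spec.dm2}},
        )
    return out


def simulate_all(config: SynthConfig) -> SynthData:
    """Run every generator off one root seed and collect the truth ledger."""
    truth = TruthLedger()
    bulk = simulate_bulk(config, truth)
    screen = simulate_screen(config, truth)
    niche_counts, niche_meta = simulate_niche(config, truth)
    lr = simulate_lr_table(config, truth)
    surv = simulate_survival(config, truth)
    synergy = simulate_synergy(config, truth)
    return SynthData(
        bulk=bulk,
        screen=screen,
        niche_counts=niche_counts,
        niche_meta=niche_meta,
        lr_table=lr,
        survival=surv,
        synergy=synergy,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# reference study conditions
# ---------------------------------------------------------------------------

def default_config(seed: int = 1) -> SynthConfig:
    """The reference synthetic study.

    Six true receptors (three shared, two AML-only, one bcCML-only) that are
    upregulated, on the surface atlas, screen dropouts, and served by planted
    niche ligands covering all four temporal classes; plus decoy receptors
    that fail exactly one cascade stage each (blacklisted, ligand-less, or
    with only non-enriched ligands). The survival panel holds 22 receptors of
    which two are prognostic. Population proportions drift the way the
    leukaemia niche remodels: MSC/osteolineage and arteriolar endothelium
    expand while sinusoidal endothelium declines.
    """
    planted_receptors = [
        PlantedReceptor("R_BOTH1", "both", 2.0),
        PlantedReceptor("R_BOTH2", "both", 2.5),
        PlantedReceptor("R_BOTH3", "both", 2.0),
        PlantedReceptor("R_AML1", "AML", 2.5),
        PlantedReceptor("R_AML2", "AML", 2.0),
        PlantedReceptor("R_BC1", "bcCML", 2.5),
    ]
    decoy_up = [  # upregulated + dropout but excluded later for one reason
        PlantedReceptor("R_BLK1", "both", 2.0),
        PlantedReceptor("R_BLK2", "AML", 2.0),
        PlantedReceptor("R_BLK3", "bcCML", 2.0),
        PlantedReceptor("R_NOLIG1", "both", 2.0),
        PlantedReceptor("R_NOLIG2", "AML", 2.0),
        PlantedReceptor("R_NOENR1", "both", 2.0),
        PlantedReceptor("R_NOENR2", "bcCML", 2.0),
    ]
    dropout_names = [p.gene for p in planted_receptors + decoy_up]
    populations = {
        "MSC": (0.15, 0.20, 0.25, 0.30),
        "osteo": (0.15, 0.18, 0.20, 0.22),
        "arteriolar": (0.20, 0.22, 0.25, 0.28),
        "sinusoidal": (0.50, 0.40, 0.30, 0.20),
    }
    planted_ligands = [
        PlantedLigand("LIG_STEADY1", ("MSC",), "steady"),
        PlantedLigand("LIG_STEADY2", ("arteriolar",), "steady"),
        PlantedLigand("LIG_LOST1", ("MSC",), "lost"),
        PlantedLigand("LIG_LOST2", ("sinusoidal",), "lost"),
        PlantedLigand("LIG_TRANS1", ("osteo",), "transient"),
        PlantedLigand("LIG_TRANS2", ("MSC",), "transient"),
        PlantedLigand("LIG_SHIFT1", ("MSC", "osteo"), "population_shift"),
        PlantedLigand("LIG_SHIFT2", ("sinusoidal", "arteriolar"), "population_shift"),
    ]
    lr_pairs = [
        LRPair("LIG_STEADY1", "R_BOTH1", True),
        LRPair("LIG_LOST1", "R_BOTH2", True),
        LRPair("LIG_TRANS1", "R_BOTH3", True),
        LRPair("LIG_SHIFT1", "R_AML1", True),
        LRPair("LIG_STEADY2", "R_AML2", True),
        LRPair("LIG_LOST2", "R_BC1", True),
        LRPair("LIG_TRANS2", "R_BOTH1", True),
        LRPair("LIG_SHIFT2", "R_AML1", True),
        # curated but never enriched: ligands stay at flat background level
        LRPair("LIG_FLAT1", "R_NOENR1", False),
        LRPair("LIG_FLAT2", "R_NOENR2", False),
        # blacklisted decoys still have nominal ligands
        LRPair("LIG_FLAT1", "R_BLK1", False),
    ]
    survival_genes = tuple(
        [p.gene for p in planted_receptors]
        + ["R_NOENR1", "R_NOENR2", "R_NOLIG1", "R_NOLIG2"]
        + [f"SVR{i:02d}" for i in range(1, 13)]
    )
    return SynthConfig(
        seed=seed,
        planted_receptors=planted_receptors + decoy_up,
        dropout_genes=[PlantedDropout(g, -1.5) for g in dropout_names],
        populations=populations,
        planted_ligands=planted_ligands,
        lr_pairs=lr_pairs,
        ligandless_receptors=["R_NOLIG1", "R_NOLIG2"],
        blacklist_genes=["R_BLK1", "R_BLK2", "R_BLK3"],
        survival=SurvivalSpec(
            genes=survival_genes,
            betas={"R_BOTH1": 0.6, "R_AML1": 0.6},
        ),
    )


def default_atlas(config: SynthConfig) -> set:
    """Surface-atlas stand-in for the default synthetic study.

    All planted receptors and decoys plus a slice of null genes, so that a
    null gene can only reach the cascade through genuine false positives.
    """
    atlas = {p.gene for p in config.planted_receptors}
    atlas |= set(config.ligandless_receptors) | set(config.blacklist_genes)
    atlas |= {g for g in config.bulk_genes() if g.startswith("G0") and g <= "G0050"}
    return atlas
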