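"""Synthetic data generators mirroring the study's data-generating structure.

The generators invert the pipeline's *metric definitions* — they do not model
digestion kinetics. A scenario fixes per-phase "true" efficiencies and
loading targets plus influent concentration envelopes; daily measurements are
drawn inside those envelopes and effluent/ammonium/biogas values are
back-computed from the truths, optionally perturbed by multiplicative
lognormal noise. Every generator is a pure function of (parameters, seed).

Microbiome data follow a Dirichlet-multinomial: a planted core of ASVs with
baseline relative abundance >= 1% (hence present in every sample), a set of
low-abundance "responder" ASVs whose log-abundance shifts linearly with a
covariate (their expected count at the sequencing depth is O(1), so the
shift moves presence/absence and is visible to unweighted UniFrac), and
background ASVs subject to an independent per-sample structural dropout so
each is absent somewhere with high probability. The phylogeny is a random
coalescent-like tree with exponential branch lengths.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_model import (
    Analyte,
    ASVTable,
    DailyOperation,
    MeasurementRecord,
    PhaseDefinition,
    ReactorConfig,
    SettlingObservation,
    Tank,
    Taxonomy,
    DEFAULT_PHASES,
    assign_phase,
)
from .errors import ValidationError
from .process_metrics import COD_PER_MOL_CH4, R_L_ATM

#: Influent envelope (mg/L) for protein-rich slaughterhouse wastewater.
DEFAULT_INFLUENT_RANGES: Mapping[str, tuple[float, float]] = {
    "TCOD": (4700.0, 6500.0),
    "SCOD": (1500.0, 3800.0),
    "NH4_N": (175.0, 420.0),
    "protein": (500.0, 1150.0),
    "carbohydrate": (100.0, 250.0),
    "FOG": (100.0, 600.0),
    "TSS": (1100.0, 3700.0),
    "VSS": (1100.0, 3500.0),
}


@dataclass(frozen=True)
class PhaseTruth:
    """True per-phase operating point and efficiencies (fractions, not %)."""

    olr: float  # g COD / L / d
    tcod_removal: float
    scod_removal: float
    ammonification_reactor: float
    ammonification_bt: float
    codch4_efficiency: float
    acidification_scod: float
    vss_conc: float  # g VSS / L in the reactor
    tss_conc: float  # g TSS / L
    srt: float  # d


#: Defaults follow the three-phase structure of the study: start-up,
#: stable operation at ~2 g COD/L/d, then loading pushed towards 6 g COD/L/d
#: with shorter retention.
DEFAULT_PHASE_TRUTHS: Mapping[str, PhaseTruth] = {
    "I": PhaseTruth(1.8, 0.78, 0.87, 0.68, 0.57, 0.79, 0.55, 6.0, 7.0, 55.0),
    "II": PhaseTruth(2.0, 0.81, 0.82, 0.82, 0.53, 0.72, 0.65, 7.9, 8.8, 115.0),
    "III": PhaseTruth(3.2, 0.83, 0.83, 0.87, 0.47, 0.70, 0.70, 9.9, 10.6, 60.0),
}


@dataclass(frozen=True)
class MicrobiomeSpec:
    """Parameters of the synthetic ASV dataset."""

    n_samples: int = 12
    n_asvs: int = 80
    core_size: int = 10
    n_responders: int = 30
    depth: int = 60_000
    effect_size: float = 2.0  # log-scale shift per unit covariate; 2.0 = "large"
    responder_mean_count: float = 2.0  # expected count at z = 0
    background_dropout: float = 0.5  # per-sample structural absence probability
    dirichlet_concentration: float = 200.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("need n_samples >= 4")
        if self.core_size + self.n_responders > self.n_asvs:
            raise ValidationError("core + responders exceed n_asvs")
        if not 0.0 <= self.background_dropout < 1.0:
            raise ValidationError("background_dropout must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete description of a synthetic AnSBR study."""

    seed: Optional[int] = None
    n_days: int = 260
    phases: tuple[PhaseDefinition, ...] = DEFAULT_PHASES
    phase_truths: Mapping[str, PhaseTruth] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_TRUTHS)
    )
    influent_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INFLUENT_RANGES)
    )
    noise_sigma: float = 0.05  # lognormal sigma on back-computed quantities
    ch4_fraction: float = 0.65
    reactor: ReactorConfig = ReactorConfig()
    vesilind_v0: float = 1.2  # m/h
    vesilind_k: float = 0.15  # L / g TSS
    microbiome: MicrobiomeSpec = MicrobiomeSpec()

    def __post_init__(self) -> None:
        for name, truth in self.phase_truths.items():
            for attr in (
                "tcod_removal", "scod_removal", "ammonification_reactor",
                "ammonification_bt", "codch4_efficiency", "acidification_scod",
            ):
                v = getattr(truth, attr)
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"phase {name}: {attr}={v} outside [0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        for lo, hi in self.influent_ranges.values():
            if not 0 <= lo <= hi:
                raise ValidationError("influent ranges must satisfy 0 <= lo <= hi")


def _mean_one_lognormal(rng: np.random.Generator, sigma: float, size=None) -> np.ndarray:
    """Multiplicative noise with unit mean (so phase means stay unbiased)."""
    if sigma == 0:
        return np.ones(size) if size else 1.0
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_reactor_timeseries(
    scenario: SyntheticScenario,
) -> tuple[list[MeasurementRecord], list[DailyOperation]]:
    """Daily measurements plus operational bookkeeping for one scenario.

    Influent concentrations are uniform inside the scenario envelope;
    effluent, ammonium and biogas values are back-computed from the phase
    truths (with mean-one lognormal noise), so the pipeline's estimators
    recover the truths exactly at sigma = 0 and unbiasedly otherwise.
    Nitrogen species are sampled weekly, CODs and gas daily.
    """
    rng = np.random.default_rng(scenario.seed)
    sigma = scenario.noise_sigma
    config = scenario.reactor
    records: list[MeasurementRecord] = []
    operations: list[DailyOperation] = []

    def uniform(key: str) -> float:
        lo, hi = scenario.influent_ranges[key]
        return float(rng.uniform(lo, hi))

    for day in range(scenario.n_days):
        phase = assign_phase(day, scenario.phases)
        truth = scenario.phase_truths[phase]
        tcod_in = uniform("TCOD")
        scod_in = min(uniform("SCOD"), tcod_in)
        fed_volume = truth.olr * config.reactor_volume / (tcod_in / 1000.0)

        def add(tank: Tank, analyte: Analyte, value: float) -> None:
            records.append(
                MeasurementRecord(day=float(day), tank=tank, analyte=analyte, value=value)
            )

        add(Tank.influent, Analyte.TCOD, tcod_in)
        add(Tank.influent, Analyte.SCOD, scod_in)
        eff_tcod = tcod_in * (1 - truth.tcod_removal) * _mean_one_lognormal(rng, sigma)
        eff_scod = scod_in * (1 - truth.scod_removal) * _mean_one_lognormal(rng, sigma)
        add(Tank.effluent, Analyte.TCOD, float(eff_tcod))
        add(Tank.effluent, Analyte.SCOD, float(eff_scod))

        if day % 7 == 0:  # weekly nitrogen and VFA sampling
            for tank, ammon in (
                (Tank.reactor, truth.ammonification_reactor),
                (Tank.buffer_tank, truth.ammonification_bt),
            ):
                tkn = float(rng.uniform(400.0, 600.0))
                add(tank, Analyte.TKN, tkn)
                add(tank, Analyte.NH4_N, float(tkn * ammon * _mean_one_lognormal(rng, sigma)))
            vfa = scod_in * truth.acidification_scod * float(_mean_one_lognormal(rng, sigma))
            add(Tank.buffer_tank, Analyte.VFA_COD, float(vfa))
            add(Tank.influent, Analyte.NH4_N, uniform("NH4_N"))
            add(Tank.influent, Analyte.protein, uniform("protein"))
            add(Tank.influent, Analyte.carbohydrate, uniform("carbohydrate"))
            add(Tank.influent, Analyte.FOG, uniform("FOG"))

        cod_fed = (tcod_in / 1000.0) * fed_volume  # g COD / d
        ch4_cod = truth.codch4_efficiency * cod_fed * float(_mean_one_lognormal(rng, sigma))
        ch4_volume = (ch4_cod / COD_PER_MOL_CH4) * R_L_ATM * config.gas_reference_temperature \
            / config.gas_reference_pressure
        add(Tank.reactor, Analyte.biogas_volume, float(ch4_volume / scenario.ch4_fraction))
        add(Tank.reactor, Analyte.ch4_fraction, scenario.ch4_fraction)

        vss_mass = truth.vss_conc * config.reactor_volume
        total_sludge = truth.tss_conc * config.reactor_volume
        operations.append(
            DailyOperation(
                day=float(day),
                influent_tcod=tcod_in,
                fed_volume=float(fed_volume),
                reactor_vss_mass=float(vss_mass),
                wasted_sludge=float(total_sludge / truth.srt),
                total_sludge=float(total_sludge),
            )
        )
    return records, operations


def generate_settling_curves(
    v0_true: float,
    k_true: float,
    X_values: Sequence[float],
    sigma_logv: float = 0.0,
    seed: Optional[int] = None,
    column_height: float = 40.0,
    settled_fraction: float = 0.45,
) -> list[SettlingObservation]:
    """Batch settling tests with velocities drawn from the Vesilind model.

    v = v0 exp(-k X) x exp(N(0, sigma_logv)) — noise is centred in log space,
    where the fit is linear. The interface trajectory descends at v until it
    reaches the hindered plateau ``settled_fraction x column_height`` (cm),
    after which it flattens. At least two distinct concentrations are
    required, otherwise the subsequent fit would be unidentifiable.
    """
    if v0_true <= 0:
        raise ValidationError("v0 must be > 0")
    X = np.asarray(list(X_values), dtype=float)
    if X.size == 0:
        raise ValidationError("X_values is empty")
    if np.unique(X).size < 2:
        raise ValidationError("need >= 2 distinct sludge concentrations")
    rng = np.random.default_rng(seed)
    observations = []
    checkpoints = np.array([15.0, 30.0, 45.0, 90.0, 120.0])
    plateau = settled_fraction * column_height
    for i, x in enumerate(X):
        v = v0_true * np.exp(-k_true * x)
        if sigma_logv > 0:
            v *= float(np.exp(rng.normal(0.0, sigma_logv)))
        v_cm_min = v * 100.0 / 60.0  # m/h -> cm/min
        depths = np.minimum(v_cm_min * checkpoints, plateau)
        observations.append(
            SettlingObservation(
                day=float(10 * i),
                sludge_concentration_X=float(x),
                trajectory=tuple(zip(checkpoints, depths)),
                measured_zsv=float(v),
            )
        )
    return observations


_PHYLA = ("Firmicutes", "Bacteroidota", "Chloroflexi", "Proteobacteria", "Halobacteriota")
_GENERA = (
    "Clostridium_sensu_stricto_1", "Proteiniclasticum", "Terrisporobacter",
    "Romboutsia", "Methanosaeta", "T34", "Brachymonas", "Lactobacillus",
)


def _random_coalescent_newick(leaf_names: Sequence[str], rng: np.random.Generator) -> str:
    """Random topology by iterative pairwise joins, Exp-distributed lengths."""
    nodes = [f"{name}" for name in leaf_names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        la, lb = rng.exponential(0.1, size=2)
        joined = f"({a}:{la:.6f},{b}:{lb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))] + [joined]
    return nodes[0] + ";"


def generate_asv_dataset(
    spec: MicrobiomeSpec,
) -> tuple[ASVTable, Taxonomy, TreeNode, pd.Series]:
    """Synthetic (counts, taxonomy, tree, covariate) with planted structure.

    See the module docstring for the generative model. The returned covariate
    is a per-sample value on [-1, 1]; responder ASVs shift their
    log-abundance by ``effect_size x covariate x (+/-1)``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_asvs
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    asv_ids = [f"ASV{j + 1:04d}" for j in range(p)]
    core_idx = np.arange(spec.core_size)
    responder_idx = np.arange(spec.core_size, spec.core_size + spec.n_responders)
    background_idx = np.arange(spec.core_size + spec.n_responders, p)

    base = np.zeros(p)
    base[core_idx] = rng.uniform(0.01, 0.05, size=spec.core_size)
    base[responder_idx] = spec.responder_mean_count / spec.depth
    if background_idx.size:
        w = rng.lognormal(0.0, 1.0, size=background_idx.size)
        remaining = max(0.05, 1.0 - base.sum())
        base[background_idx] = remaining * w / w.sum()
    base = base / base.sum()

    covariate = np.linspace(-1.0, 1.0, n)
    loadings = np.where(np.arange(spec.n_responders) % 2 == 0, 1.0, -1.0)

    counts = np.zeros((n, p), dtype=np.int64)
    for s in range(n):
        logw = np.log(base)
        logw[responder_idx] += spec.effect_size * covariate[s] * loadings
        w = np.exp(logw)
        if spec.background_dropout > 0 and background_idx.size:
            drop = rng.random(background_idx.size) < spec.background_dropout
            w[background_idx[drop]] = 0.0
        w = w / w.sum()
        alpha = spec.dirichlet_concentration * w
        probs = np.zeros(p)
        pos = alpha > 0
        g = rng.gamma(alpha[pos], 1.0)
        probs[pos] = g / g.sum()
        counts[s] = rng.multinomial(spec.depth, probs)
    # the planted core must be present everywhere by construction
    core_presence = (counts[:, core_idx] > 0).all(axis=0)
    if not core_presence.all():  # pragma: no cover - astronomically unlikely
        raise ValidationError("planted core ASV absent from a sample; increase depth")

    assignments = {}
    for j, asv in enumerate(asv_ids):
        genus = None if rng.random() < 0.1 else _GENERA[j % len(_GENERA)]
        assignments[asv] = {"phylum": _PHYLA[j % len(_PHYLA)], "genus": genus}
    taxonomy = Taxonomy(assignments)

    tree = TreeNode.read(_io.StringIO(_random_coalescent_newick(asv_ids, rng)))

    metadata = {
        sid: {"tank": "reactor", "day": float(d)}
        for sid, d in zip(sample_ids, np.linspace(0, 259, n).round())
    }
    table = ASVTable(sample_ids, asv_ids, counts, metadata)
    cov = pd.Series(covariate, index=sample_ids, name="covariate")
    return table, taxonomy, tree, cov


def planted_core_ids(spec: MicrobiomeSpec) -> frozenset[str]:
    """The ASV ids the generator plants as core (first ``core_size`` ids)."""
    return frozenset(f"ASV{j + 1:04d}" for j in range(spec.core_size))
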