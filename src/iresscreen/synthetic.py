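"""Synthetic screen generator with known ground truth.

Emulates the structure of an arrayed siRNA screen read out by reporter-mRNA
luminescence: 96-well plates carrying four scrambled (non-targeting) negative
control wells plus firefly-luciferase and PLK1 positive-control wells, three
siRNAs per gene each assayed on three replicate plates, a multiplicative
per-plate effect, log-normal well noise, and planted positive/negative
regulators with per-siRNA knockdown efficiencies.  Companion generators
produce the secondary-screen channels (IRES reporter, cap reporter, ATP
viability), qPCR Ct tables with amplification efficiencies, and group-labelled
ELISA concentration tables.

Signal model (primary screen, IRES channel):

    raw = baseline * plate_effect * gene_effect * noise

where ``plate_effect = exp(N(0, plate_effect_sd))``, ``noise`` is log-normal
with unit mean and coefficient of variation ``noise_cv``, and for a planted
regulator with effect multiplier ``m`` silenced by an siRNA with knockdown
efficiency ``k``, ``gene_effect = 1 + k * (m - 1)``.  Neutral genes and
scrambled controls have ``gene_effect = 1``; FLuc-siRNA control wells are
strongly silenced (x0.05) and PLK1 control wells reflect the viability loss of
PLK1 knockdown (x0.25).

The library is plated siRNA-set-major (all first siRNAs, then all second,
then all third), mirroring how commercial siRNA libraries ship as separate
plate sets; a gene's three reagents therefore land on different plates.

All randomness derives from ``SimulationConfig.seed`` through named
``numpy.random.SeedSequence`` child streams, so each generator is
reproducible in isolation and identical seed + config gives bit-identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import screen_io as sio
from .errors import IntegrityError, ParameterError, SizingError

__all__ = [
    "PlantedRegulator",
    "SimulationConfig",
    "GroundTruth",
    "simulate_primary_screen",
    "simulate_secondary_screen",
    "simulate_qpcr",
    "simulate_elisa",
]

# Control-well effect multipliers on the luciferase channel.  FLuc siRNA
# silences the reporter itself; PLK1 knockdown arrests cells in prometaphase,
# reducing both viability (ATP ~25% of control) and reporter output.
FLUC_CONTROL_EFFECT = 0.05
PLK1_CONTROL_EFFECT = 0.25

# Fixed control positions: corner wells for scrambled controls (extendable),
# B1 for the FLuc siRNA, G12 for PLK1.
_SCRAMBLED_POSITIONS = ("A1", "A12", "H1", "H12", "D1", "D12", "E1", "E12")
_FLUC_POSITION = "B1"
_PLK1_POSITION = "G12"

_QPCR_TARGET_BASE_CT = 22.0
_QPCR_REFERENCE_BASE_CT = 17.0


@dataclass(frozen=True)
class PlantedRegulator:
    """Ground-truth regulator planted into the simulated screen.

    ``effect_multiplier`` is the fold-change of reporter signal at complete
    knockdown: >1 for negative regulators of IRES activity (Up hits), <1 for
    positive regulators (Down hits).  ``ires_specific`` regulators leave the
    cap-reporter channel untouched; ``toxic`` genes depress all three
    secondary channels jointly (viability phenotype).
    """

    gene_symbol: str
    effect_multiplier: float
    ires_specific: bool = False
    toxic: bool = False

    def __post_init__(self):
        if not self.effect_multiplier > 0:
            raise ParameterError(
                f"effect_multiplier must be > 0, got {self.effect_multiplier}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated screen; defaults follow the screened study
    conditions (3 siRNAs/gene, triplicate plates, 4 scrambled controls)."""

    n_genes: int
    sirnas_per_gene: int = 3
    replicate_plates: int = 3
    wells_per_plate: int = 96
    n_neg_controls_per_plate: int = 4
    noise_cv: float = 0.15
    plate_effect_sd: float = 0.10
    baseline_signal: float = 10_000.0
    planted_regulators: tuple[PlantedRegulator, ...] = ()
    knockdown_efficiency_range: tuple[float, float] = (0.80, 0.95)
    kinase_fraction: float = 0.702
    seed: int = 0
    max_plates: int | None = None

    def __post_init__(self):
        if self.n_genes < 0:
            raise ParameterError(f"n_genes must be >= 0, got {self.n_genes}")
        if self.sirnas_per_gene < 1 or self.replicate_plates < 1:
            raise ParameterError("sirnas_per_gene and replicate_plates must be >= 1")
        if self.wells_per_plate != sio.PLATE_ROWS * sio.PLATE_COLS:
            raise ParameterError("only 96-well (8x12) plates are supported")
        if self.n_neg_controls_per_plate < 1:
            raise ParameterError("need at least 1 scrambled control well per plate")
        if self.n_neg_controls_per_plate > len(_SCRAMBLED_POSITIONS):
            raise ParameterError(
                f"at most {len(_SCRAMBLED_POSITIONS)} scrambled wells supported"
            )
        if self.noise_cv < 0 or self.plate_effect_sd < 0:
            raise ParameterError("noise_cv and plate_effect_sd must be >= 0")
        if not self.baseline_signal > 0:
            raise ParameterError("baseline_signal must be positive")
        lo, hi = self.knockdown_efficiency_range
        if not (0 <= lo <= hi <= 1):
            raise ParameterError(
                f"knockdown_efficiency_range must satisfy 0 <= lo <= hi <= 1, "
                f"got ({lo}, {hi})"
            )
        names = [p.gene_symbol for p in self.planted_regulators]
        if len(names) != len(set(names)):
            raise ParameterError("planted_regulators contains duplicate genes")

    @property
    def reactions_per_plate(self) -> int:
        """Gene wells available on one plate after control positions."""
        return self.wells_per_plate - self.n_neg_controls_per_plate - 2

    def rng(self, stream: str) -> np.random.Generator:
        """Named child random stream derived from the master seed."""
        streams = ("library", "knockdown", "plate_effects", "well_noise",
                   "secondary", "qpcr", "elisa")
        if stream not in streams:
            raise ParameterError(f"unknown random stream {stream!r}")
        children = np.random.SeedSequence(self.seed).spawn(len(streams))
        return np.random.default_rng(children[streams.index(stream)])


@dataclass
class GroundTruth:
    """Planted truth of a simulated screen.

    ``genes``: per-gene regulator sign ('positive'/'negative'/'none'), effect
    multiplier, ires_specific and toxic flags.  ``knockdown``: per-reagent
    knockdown efficiency, needed to reconstruct each well analytically.
    """

    genes: pd.DataFrame
    knockdown: pd.DataFrame = field(repr=False)

    def regulators(self) -> pd.DataFrame:
        return self.genes[self.genes["sign"] != "none"]


def gene_names(config: SimulationConfig) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(config.n_genes)]


def _make_library(config: SimulationConfig) -> pd.DataFrame:
    rng = config.rng("library")
    names = gene_names(config)
    n_kinase = int(round(config.kinase_fraction * config.n_genes))
    classes = ["kinase"] * n_kinase + ["phosphatase"] * (config.n_genes - n_kinase)
    rows = []
    bases = np.array(list("ACGU"))
    for gi, (gene, cls) in enumerate(zip(names, classes)):
        for s in range(1, config.sirnas_per_gene + 1):
            sense = "".join(rng.choice(bases, size=21))
            anti = "".join(rng.choice(bases, size=21))
            rows.append((gene, f"NM_{gi + 1:06d}", s, sense, anti, cls))
    return pd.DataFrame(rows, columns=sio.LIBRARY_COLUMNS)


def _truth_tables(config: SimulationConfig) -> GroundTruth:
    planted = {p.gene_symbol: p for p in config.planted_regulators}
    names = gene_names(config)
    unknown = set(planted) - set(names)
    if unknown:
        raise IntegrityError(
            f"planted regulators not in the simulated library: {sorted(unknown)}"
        )
    rows = []
    for g in names:
        p = planted.get(g)
        if p is None:
            rows.append((g, "none", 1.0, False, False))
        else:
            # Up hit (multiplier > 1) = silencing raises IRES output = the
            # gene normally represses it = negative regulator, and vice versa.
            sign = "negative" if p.effect_multiplier > 1 else (
                "positive" if p.effect_multiplier < 1 else "none")
            rows.append((g, sign, p.effect_multiplier, p.ires_specific, p.toxic))
    genes = pd.DataFrame(
        rows, columns=["gene_symbol", "sign", "effect_multiplier",
                       "ires_specific", "toxic"],
    )
    rng = config.rng("knockdown")
    lo, hi = config.knockdown_efficiency_range
    kd_rows = []
    for g in names:
        for s in range(1, config.sirnas_per_gene + 1):
            kd_rows.append((g, s, float(rng.uniform(lo, hi))))
    knockdown = pd.DataFrame(kd_rows, columns=["gene_symbol", "sirna_index", "efficiency"])
    return GroundTruth(genes=genes, knockdown=knockdown)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of
    variation ``cv``; exactly 1 everywhere when cv == 0."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _plate_effects(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sd, size=size))


def _base_plate_layouts(config: SimulationConfig) -> pd.DataFrame:
    """One layout per base plate (replicate_index 0); reactions are assigned
    siRNA-set-major so sibling reagents of a gene fall on different plates."""
    control_wells = set(_SCRAMBLED_POSITIONS[: config.n_neg_controls_per_plate])
    control_wells |= {_FLUC_POSITION, _PLK1_POSITION}
    gene_wells = [
        sio.format_well(r, c)
        for r in range(sio.PLATE_ROWS)
        for c in range(sio.PLATE_COLS)
        if sio.format_well(r, c) not in control_wells
    ]
    capacity = len(gene_wells)
    reactions = [
        (g, s)
        for s in range(1, config.sirnas_per_gene + 1)
        for g in gene_names(config)
    ]
    n_base = max(1, math.ceil(len(reactions) / capacity)) if capacity else 0
    if capacity <= 0:
        raise SizingError(
            f"no gene wells available: {config.wells_per_plate} wells, "
            f"{len(control_wells)} control positions"
        )
    if config.max_plates is not None:
        needed = n_base * config.replicate_plates
        if needed > config.max_plates:
            raise SizingError(
                f"screen needs {len(reactions)} reaction wells on {needed} "
                f"plates but only {config.max_plates} plates "
                f"({config.max_plates * capacity} gene wells) are available"
            )
    rows = []
    for b in range(n_base):
        chunk = reactions[b * capacity: (b + 1) * capacity]
        plate = f"P{b + 1:03d}"
        for pos in _SCRAMBLED_POSITIONS[: config.n_neg_controls_per_plate]:
            rows.append((plate, 0, pos, sio.CONTENT_SCRAMBLED, None, None))
        rows.append((plate, 0, _FLUC_POSITION, sio.CONTENT_FLUC, None, None))
        rows.append((plate, 0, _PLK1_POSITION, sio.CONTENT_PLK1, None, None))
        for (g, s), well in zip(chunk, gene_wells):
            rows.append((plate, 0, well, sio.CONTENT_GENE, g, s))
    return pd.DataFrame(rows, columns=sio.LAYOUT_COLUMNS)


def _gene_effects(layout: pd.DataFrame, truth: GroundTruth) -> np.ndarray:
    """Deterministic per-well effect multiplier from the planted truth."""
    mult = truth.genes.set_index("gene_symbol")["effect_multiplier"]
    kd = truth.knockdown.set_index(["gene_symbol", "sirna_index"])["efficiency"]
    effects = np.ones(len(layout))
    is_gene = (layout["content_type"] == sio.CONTENT_GENE).to_numpy()
    if is_gene.any():
        genes = layout.loc[is_gene, "gene_symbol"]
        sidx = layout.loc[is_gene, "sirna_index"].astype(int)
        m = mult.loc[genes].to_numpy()
        k = kd.loc[list(zip(genes, sidx))].to_numpy()
        effects[is_gene] = 1.0 + k * (m - 1.0)
    effects[(layout["content_type"] == sio.CONTENT_FLUC).to_numpy()] = FLUC_CONTROL_EFFECT
    effects[(layout["content_type"] == sio.CONTENT_PLK1).to_numpy()] = PLK1_CONTROL_EFFECT
    return effects


def simulate_primary_screen(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a complete primary screen.

    Returns ``(library, layouts, measurements, truth)``: the siRNA library
    table, the plate layouts (every base plate replicated
    ``config.replicate_plates`` times), the raw IRES-channel luminescence
    table, and the planted :class:`GroundTruth`.
    """
    library = _make_library(config)
    truth = _truth_tables(config)
    base = _base_plate_layouts(config)

    layouts = []
    for rep in range(1, config.replicate_plates + 1):
        lay = base.copy()
        lay["plate_id"] = lay["plate_id"] + f"-R{rep}"
        lay["replicate_index"] = rep
        layouts.append(lay)
    layout = pd.concat(layouts, ignore_index=True)

    plate_ids = layout["plate_id"].unique()
    pe = _plate_effects(config.rng("plate_effects"), config.plate_effect_sd,
                        len(plate_ids))
    plate_effect = pd.Series(pe, index=plate_ids)

    effects = _gene_effects(layout, truth)
    noise = _lognormal_noise(config.rng("well_noise"), config.noise_cv, len(layout))
    values = (config.baseline_signal
              * plate_effect.loc[layout["plate_id"]].to_numpy()
              * effects * noise)
    measurements = pd.DataFrame({
        "plate_id": layout["plate_id"],
        "well": layout["well"],
        "channel": sio.CHANNEL_IRES,
        "value": values,
    })
    return library, layout, measurements, truth


def simulate_secondary_screen(
    config: SimulationConfig, genes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the three-channel secondary screen for the given hit genes.

    Each gene is re-assayed in three channels: IRES reporter, cap reporter,
    and ATP viability, on channel-specific plates carrying scrambled
    controls.  The planted per-gene effect multiplier is applied directly
    (re-testing uses the validated reagent, so no per-siRNA knockdown
    scaling): ires_specific regulators perturb only the IRES channel,
    non-specific regulators both reporter channels, and toxic genes depress
    all three channels jointly.

    Returns ``(layouts, measurements)``.
    """
    if not genes:
        raise ParameterError("secondary screen needs a nonempty gene list")
    known = set(gene_names(config))
    unknown = [g for g in genes if g not in known]
    if unknown:
        raise IntegrityError(f"unknown gene_id(s) in secondary screen: {unknown[:5]}")
    truth = _truth_tables(config)
    tg = truth.genes.set_index("gene_symbol")

    control_positions = _SCRAMBLED_POSITIONS[: config.n_neg_controls_per_plate]
    control_wells = set(control_positions)
    gene_wells = [
        sio.format_well(r, c)
        for r in range(sio.PLATE_ROWS)
        for c in range(sio.PLATE_COLS)
        if sio.format_well(r, c) not in control_wells
    ]
    capacity = len(gene_wells)

    rng = config.rng("secondary")
    lay_rows, meas_rows = [], []
    for channel in sio.CHANNELS:
        for b in range(max(1, math.ceil(len(genes) / capacity))):
            chunk = genes[b * capacity: (b + 1) * capacity]
            wells = list(control_positions) + gene_wells[: len(chunk)]
            contents = ([sio.CONTENT_SCRAMBLED] * len(control_positions)
                        + [sio.CONTENT_GENE] * len(chunk))
            gsyms = [None] * len(control_positions) + list(chunk)
            effects = np.ones(len(wells))
            for i, g in enumerate(chunk):
                row = tg.loc[g]
                m = float(row["effect_multiplier"])
                if bool(row["toxic"]):
                    e = m  # joint viability loss hits every channel
                elif channel == sio.CHANNEL_IRES:
                    e = m
                elif channel == sio.CHANNEL_CAP:
                    e = 1.0 if bool(row["ires_specific"]) else m
                else:  # ATP: non-toxic regulators leave viability intact
                    e = 1.0
                effects[len(control_positions) + i] = e
            # like the primary screen, each reaction runs on replicate plates
            for rep in range(1, config.replicate_plates + 1):
                plate = f"S{b + 1:02d}-{channel}-R{rep}"
                noise = _lognormal_noise(rng, config.noise_cv, len(wells))
                values = config.baseline_signal * effects * noise
                for w, ct, g in zip(wells, contents, gsyms):
                    lay_rows.append((plate, rep, w, ct, g,
                                     1 if ct == sio.CONTENT_GENE else None))
                for w, v in zip(wells, values):
                    meas_rows.append((plate, w, channel, v))
    layout = pd.DataFrame(lay_rows, columns=sio.LAYOUT_COLUMNS)
    measurements = pd.DataFrame(meas_rows, columns=sio.MEASUREMENT_COLUMNS)
    return layout, measurements


def simulate_qpcr(
    config: SimulationConfig,
    true_ratio: float,
    efficiency: float,
    n_per_group: int,
    ct_noise_sd: float = 0.15,
    target_gene: str = "TARGET",
    reference_gene: str = "ACTB",
) -> pd.DataFrame:
    """Generate a paired-target/reference Ct table for two groups.

    Control-group target Cts sit at a fixed baseline; treated-group target
    Cts are shifted by ``dCt = -log(true_ratio)/log(efficiency)`` so that the
    efficiency-corrected expression ratio of treated vs control equals
    ``true_ratio``.  Reference-gene Cts are unshifted.  Gaussian Ct noise.
    """
    if not true_ratio > 0:
        raise ParameterError(f"true_ratio must be > 0, got {true_ratio}")
    if not 1.0 < efficiency <= 2.0:
        raise ParameterError(
            f"amplification efficiency must be in (1, 2], got {efficiency}"
        )
    if n_per_group < 2:
        raise ParameterError("need at least 2 samples per group")
    if ct_noise_sd < 0:
        raise ParameterError("ct_noise_sd must be >= 0")
    rng = config.rng("qpcr")
    shift = -math.log(true_ratio) / math.log(efficiency)
    rows = []
    for group, dct in (("control", 0.0), ("treated", shift)):
        for i in range(n_per_group):
            sid = f"{group}_{i + 1}"
            tnoise = float(rng.normal(0, ct_noise_sd)) if ct_noise_sd else 0.0
            rnoise = float(rng.normal(0, ct_noise_sd)) if ct_noise_sd else 0.0
            rows.append((sid, group, target_gene, "target",
                         _QPCR_TARGET_BASE_CT + dct + tnoise, efficiency))
            rows.append((sid, group, reference_gene, "reference",
                         _QPCR_REFERENCE_BASE_CT + rnoise, efficiency))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene_symbol", "role", "ct", "efficiency"]
    )


def simulate_elisa(
    config: SimulationConfig,
    control_mean: float,
    percent_reduction: float,
    n_per_group: int,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Generate a two-group ELISA concentration table.

    Treated mean = ``control_mean * (1 - percent_reduction)`` plus Gaussian
    noise (default SD 5% of the control mean).
    """
    if not 0 <= percent_reduction < 1:
        raise ParameterError(
            f"percent_reduction must be in [0, 1), got {percent_reduction}"
        )
    if n_per_group < 2:
        raise ParameterError("downstream t-test needs >= 2 samples per group")
    if noise_sd is None:
        noise_sd = 0.05 * control_mean
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = config.rng("elisa")
    rows = []
    for group, mean in (("control", control_mean),
                        ("treated", control_mean * (1 - percent_reduction))):
        for _ in range(n_per_group):
            noise = float(rng.normal(0, noise_sd)) if noise_sd else 0.0
            rows.append((group, mean + noise))
    return pd.DataFrame(rows, columns=["group", "concentration"])
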