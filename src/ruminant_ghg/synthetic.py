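"""Synthetic chamber, community and nutrient data with the statistical
structure the analysis assumes.

The generator stands in for the field experiment: 12 yaks split over two
feeding regimes (traditional grazing TG, warm-grazing + cold-indoor-feeding
WGCF) observed as three season-groups (YWG warm grazing, YCG cold grazing,
YCF cold indoor feeding, n = 6 each).

* Chamber sessions: near-linear concentration ramps whose slope is the exact
  algebraic inverse of the flux equation at the spec'd chamber constants,
  plus additive Gaussian noise; a configurable fraction of sessions are
  exponential-saturation failures that the R^2 gate should reject.
* Count tables: per-sample compositions drawn from group-specific means via
  a Dirichlet-multinomial (concentration theta * mean), sequencing depth
  uniform over a range. The taxonomy includes the rumen taxa a practitioner
  expects (Prevotella, Ruminococcus, Methanobrevibacter, ...), and the
  group contrasts hold in expectation (e.g. Neocallimastigomycota and
  Methanobrevibacter enriched under cold indoor feeding).
* Nutrient tables default to the experiment's point values per diet.

Default true emission rates are the study-scale day emissions divided by
24 h, i.e. a flat diurnal profile; per-animal rates scatter around the group
mean with a lognormal coefficient of variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ruminant_ghg.community import CountTable, RANKS
from ruminant_ghg.flux import ChamberSession, DEFAULT_VOLUME_M3, P0_PA, slope_for_flux

GROUPS = ("YWG", "YCG", "YCF")
KINGDOMS = ("bacteria", "fungi", "archaea")

#: group -> season
GROUP_SEASON = {"YWG": "warm", "YCG": "cold", "YCF": "cold"}
#: group -> regimes the group contributes to
GROUP_REGIMES = {"YWG": frozenset({"TG", "WGCF"}), "YCG": frozenset({"TG"}), "YCF": frozenset({"WGCF"})}

#: default true emission rates, g head^-1 h^-1: day emission / 24 h
DEFAULT_TRUE_RATE = {
    ("YWG", "CO2"): 1729.80 / 24.0,
    ("YCG", "CO2"): 1345.18 / 24.0,
    ("YCF", "CO2"): 2160.17 / 24.0,
    ("YWG", "CH4"): 56.18 / 24.0,
    ("YCG", "CH4"): 29.94 / 24.0,
    ("YCF", "CH4"): 46.03 / 24.0,
}

#: ambient baseline concentration at chamber closure, ppm
BASELINE_PPM = {"CO2": 420.0, "CH4": 2.0}

#: diet nutrient point values per group, % of dry matter
DEFAULT_NUTRIENTS = pd.DataFrame(
    {
        "DM": [95.81, 96.69, 96.57],
        "CP": [9.96, 4.35, 9.91],
        "NDF": [56.40, 62.73, 52.98],
        "ADF": [27.82, 38.07, 30.67],
        "OM": [91.84, 93.27, 93.28],
    },
    index=pd.Index(GROUPS, name="group"),
)

# genus -> (domain, phylum, class, order, family), mean proportion per group.
# Proportions per group sum to 1; contrasts mirror the qualitative enrichment
# pattern of the experiment (magnitudes are free parameters).
_BACTERIA = {
    # genus: lineage-head, (YWG, YCG, YCF)
    "Prevotella": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", (0.20, 0.20, 0.26)),
    "Bacteroides": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", (0.10, 0.06, 0.05)),
    "Rikenellaceae_RC9": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", (0.16, 0.20, 0.15)),
    "Ruminococcus": ("Bacteria", "Firmicutes", "Clostridia", "Oscillospirales", "Ruminococcaceae", (0.10, 0.10, 0.14)),
    "Butyrivibrio": ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", (0.10, 0.09, 0.05)),
    "Selenomonas": ("Bacteria", "Firmicutes", "Negativicutes", "Selenomonadales", "Selenomonadaceae", (0.04, 0.08, 0.07)),
    "Succiniclasticum": ("Bacteria", "Firmicutes", "Negativicutes", "Acidaminococcales", "Acidaminococcaceae", (0.06, 0.04, 0.06)),
    "Christensenellaceae_R7": ("Bacteria", "Firmicutes", "Clostridia", "Christensenellales", "Christensenellaceae", (0.18, 0.17, 0.16)),
    "Fibrobacter": ("Bacteria", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", (0.02, 0.02, 0.04)),
    "Succinivibrio": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", (0.03, 0.03, 0.01)),
    "Desulfovibrio": ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae", (0.01, 0.01, 0.01)),
}

_FUNGI = {
    "Aspergillus": ("Eukaryota", "Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae", (0.25, 0.35, 0.20)),
    "Leptosphaeria": ("Eukaryota", "Ascomycota", "Dothideomycetes", "Pleosporales", "Leptosphaeriaceae", (0.10, 0.15, 0.08)),
    "Claviceps": ("Eukaryota", "Ascomycota", "Sordariomycetes", "Hypocreales", "Clavicipitaceae", (0.05, 0.08, 0.10)),
    "Fusarium": ("Eukaryota", "Ascomycota", "Sordariomycetes", "Hypocreales", "Nectriaceae", (0.225, 0.125, 0.15)),
    "Cystofilobasidium": ("Eukaryota", "Basidiomycota", "Tremellomycetes", "Cystofilobasidiales", "Cystofilobasidiaceae", (0.20, 0.15, 0.18)),
    "Vishniacozyma": ("Eukaryota", "Basidiomycota", "Tremellomycetes", "Tremellales", "Bulleribasidiaceae", (0.15, 0.12, 0.14)),
    "Orpinomyces": ("Eukaryota", "Neocallimastigomycota", "Neocallimastigomycetes", "Neocallimastigales", "Neocallimastigaceae", (0.01, 0.01, 0.08)),
    "Neocallimastix": ("Eukaryota", "Neocallimastigomycota", "Neocallimastigomycetes", "Neocallimastigales", "Neocallimastigaceae", (0.01, 0.01, 0.05)),
    "Pecoramyces": ("Eukaryota", "Neocallimastigomycota", "Neocallimastigomycetes", "Neocallimastigales", "Neocallimastigaceae", (0.005, 0.005, 0.02)),
}

_ARCHAEA = {
    "Methanobrevibacter": ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", (0.55, 0.50, 0.70)),
    "Methanobacterium": ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", (0.20, 0.25, 0.08)),
    "Methanosphaera": ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", (0.12, 0.12, 0.10)),
    "Methanomicrobium": ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanomicrobiaceae", (0.08, 0.08, 0.07)),
    "Methanimicrococcus": ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanosarcinales", "Methanosarcinaceae", (0.04, 0.04, 0.04)),
    "Nitrososphaera": ("Archaea", "Thaumarchaeota", "Nitrososphaeria", "Nitrososphaerales", "Nitrososphaeraceae", (0.01, 0.01, 0.01)),
}

_KINGDOM_TAXA = {"bacteria": _BACTERIA, "fungi": _FUNGI, "archaea": _ARCHAEA}

#: Dirichlet concentration per kingdom: moderate within-group overdispersion
DEFAULT_THETA = {"bacteria": 150.0, "fungi": 80.0, "archaea": 150.0}


def default_community(kingdom: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(group mean compositions [taxa x groups], lineage frame) for a kingdom."""
    taxa = _KINGDOM_TAXA[kingdom]
    comp = pd.DataFrame(
        {genus: list(spec[5]) for genus, spec in taxa.items()},
        index=list(GROUPS),
    ).T
    lineage = pd.DataFrame(
        {genus: list(spec[:5]) + [genus] for genus, spec in taxa.items()},
        index=list(RANKS),
    ).T
    comp.index = [f"ASV_{g}" for g in comp.index]
    lineage.index = [f"ASV_{g}" for g in lineage.index]
    sums = comp.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise AssertionError(f"{kingdom} compositions do not sum to 1: {sums.to_dict()}")
    return comp, lineage


@dataclass
class SyntheticSpec:
    """The stated world for the generator; defaults mirror the experiment."""

    true_rate: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_RATE))
    noise_sd_ppm: float = 2.0
    volume_m3: float = DEFAULT_VOLUME_M3
    n_heads: int = 1
    pressure_pa: float = 70000.0  # ~3000 m altitude
    temp_c: float = 10.0
    n_sessions_per_day: int = 12
    session_minutes: float = 20.0
    sample_interval_s: float = 60.0
    fail_fraction: float = 0.1
    theta: dict = field(default_factory=lambda: dict(DEFAULT_THETA))
    depth_range: tuple[int, int] = (30_000, 70_000)
    animal_cv: float = 0.10  # between-animal lognormal CV of true rates
    n_per_group: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fail_fraction < 1:
            raise ValueError("fail_fraction must be in [0, 1)")
        if self.depth_range[0] < 100:
            raise ValueError("minimum depth must be >= 100")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must be (min, max) with min <= max")
        for theta in self.theta.values():
            if theta is not None and theta <= 0:
                raise ValueError("overdispersion theta must be positive (or None for exact means)")
        if self.volume_m3 <= 0 or self.n_heads < 1:
            raise ValueError("chamber volume must be positive and n_heads >= 1")


@dataclass
class GroundTruth:
    """Everything parameter-recovery tests need, serialisable to JSON."""

    true_rate_group: dict  # "group|gas" -> g head^-1 h^-1
    true_rate_animal: dict  # "animal|gas" -> g head^-1 h^-1
    compositions: dict  # kingdom -> {feature -> {group -> proportion}}
    nutrients: dict  # group -> {column -> value}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def default_metadata(n_per_group: int = 6) -> pd.DataFrame:
    """Sample metadata: 2 regimes x 6 animals observed as 3 season-groups.

    Warm-season samples (YWG) come from half the TG and half the WGCF
    animals; cold-season samples split by regime into YCG (grazing) and YCF
    (indoor feeding).
    """
    half = n_per_group // 2
    tg_animals = [f"T{i + 1:02d}" for i in range(n_per_group)]
    wgcf_animals = [f"W{i + 1:02d}" for i in range(n_per_group)]
    rows = []
    ywg_animals = tg_animals[:half] + wgcf_animals[:half]
    for i, animal in enumerate(ywg_animals):
        rows.append(("YWG", f"YWG_{i + 1}", animal))
    for i, animal in enumerate(tg_animals):
        rows.append(("YCG", f"YCG_{i + 1}", animal))
    for i, animal in enumerate(wgcf_animals):
        rows.append(("YCF", f"YCF_{i + 1}", animal))
    return pd.DataFrame(
        [
            {
                "sample_id": sid,
                "group": group,
                "season": GROUP_SEASON[group],
                "regime_membership": "|".join(sorted(GROUP_REGIMES[group])),
                "animal_id": animal,
            }
            for group, sid, animal in rows
        ]
    )


def _chamber_kwargs(spec: SyntheticSpec) -> dict:
    return dict(
        volume_m3=spec.volume_m3,
        n_heads=spec.n_heads,
        pressure_pa=spec.pressure_pa,
        temp_c=spec.temp_c,
        p0_pa=P0_PA,
    )


def simulate_chamber_session(
    spec: SyntheticSpec,
    animal: str,
    gas: str,
    rng,
    true_rate: float | None = None,
    group: str | None = None,
    start_hour: float = 0.0,
    force_fail: bool | None = None,
) -> ChamberSession:
    """One sealed-chamber concentration series for an animal and gas.

    The linear ramp slope is the exact inverse of the flux equation at the
    spec's chamber constants; with probability ``fail_fraction`` (or when
    ``force_fail``) an exponential saturation c0 + a(1 - e^{-t/tau}) with
    tau = session/3 replaces the ramp, exercising the R^2 QC gate.
    """
    rng = np.random.default_rng(rng)
    if true_rate is None:
        key = (group or "YWG", gas)
        if key not in spec.true_rate:
            raise KeyError(f"no true rate for {key}")
        true_rate = spec.true_rate[key]
    duration = spec.session_minutes * 60.0
    times = np.arange(0.0, duration + spec.sample_interval_s / 2, spec.sample_interval_s)
    template = ChamberSession(
        session_id="template", animal_id=animal, gas=gas,
        times=times, concentrations=np.zeros_like(times), **_chamber_kwargs(spec),
    )
    slope = slope_for_flux(true_rate, template)
    c0 = BASELINE_PPM[gas]
    fail = force_fail if force_fail is not None else bool(rng.random() < spec.fail_fraction)
    if fail:
        tau = duration / 3.0
        ramp = c0 + slope * duration * (1.0 - np.exp(-times / tau))
    else:
        ramp = c0 + slope * times
    noise = rng.normal(0.0, spec.noise_sd_ppm, times.size) if spec.noise_sd_ppm > 0 else 0.0
    return ChamberSession(
        session_id=f"{animal}_{gas}_h{start_hour:04.1f}",
        animal_id=animal,
        gas=gas,
        times=times,
        concentrations=ramp + noise,
        **_chamber_kwargs(spec),
    )


def simulate_chamber_day(
    spec: SyntheticSpec, animal: str, gas: str, rng, true_rate: float, group: str
) -> list[ChamberSession]:
    """The full 12-measurement daily protocol (one session every 2 h)."""
    rng = np.random.default_rng(rng)
    hours = np.arange(spec.n_sessions_per_day) * 24.0 / spec.n_sessions_per_day
    return [
        simulate_chamber_session(
            spec, animal, gas, rng, true_rate=true_rate, group=group, start_hour=h
        )
        for h in hours
    ]


def simulate_counts(
    spec: SyntheticSpec, metadata: pd.DataFrame, kingdom: str, rng
) -> CountTable:
    """Dirichlet-multinomial ASV counts for every sample in ``metadata``.

    Per sample: p ~ Dirichlet(theta * group mean), counts ~ Multinomial(depth, p),
    depth ~ uniform integer over ``depth_range``. ``theta=None`` uses the
    group mean exactly (the theta -> infinity limit).
    """
    rng = np.random.default_rng(rng)
    comp, lineage = default_community(kingdom)
    theta = spec.theta.get(kingdom)
    cols = {}
    for _, row in metadata.iterrows():
        mean = comp[row["group"]].to_numpy()
        if theta is None:
            p = mean
        else:
            p = rng.dirichlet(theta * mean)
        depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
        cols[row["sample_id"]] = rng.multinomial(depth, p)
    counts = pd.DataFrame(cols, index=comp.index)
    return CountTable(counts, lineage, kingdom)


def simulate_nutrients(spec: SyntheticSpec, means: pd.DataFrame | None = None) -> pd.DataFrame:
    """Diet nutrient table; defaults to the experiment's point values."""
    table = (means if means is not None else DEFAULT_NUTRIENTS).copy()
    table.index.name = "group"
    return table


def simulate_dataset(spec: SyntheticSpec, out_dir: str | Path | None = None):
    """Generate the complete synthetic experiment.

    Returns ``(sessions, metadata, tables, nutrients, truth)`` where
    ``tables`` maps kingdom -> CountTable. With ``out_dir`` set, also writes
    chamber_series.csv, counts/taxonomy TSVs per kingdom, metadata.tsv,
    nutrients.tsv and ground_truth.json.
    """
    from ruminant_ghg import io  # local import to keep module layering acyclic

    root = np.random.SeedSequence(spec.seed)
    ss_animal, ss_chamber, ss_counts = root.spawn(3)
    rng_animal = np.random.default_rng(ss_animal)
    rng_chamber = np.random.default_rng(ss_chamber)

    metadata = default_metadata(spec.n_per_group)
    # per-animal true rates: lognormal scatter around the group mean
    true_animal: dict[str, float] = {}
    sessions: list[ChamberSession] = []
    sigma = np.sqrt(np.log(1.0 + spec.animal_cv**2)) if spec.animal_cv > 0 else 0.0
    for _, row in metadata.iterrows():
        for gas in ("CO2", "CH4"):
            base = spec.true_rate[(row["group"], gas)]
            factor = float(np.exp(rng_animal.normal(-sigma**2 / 2, sigma))) if sigma else 1.0
            rate = base * factor
            true_animal[f"{row['sample_id']}|{gas}"] = rate
            day = simulate_chamber_day(
                spec, row["animal_id"], gas, rng_chamber, true_rate=rate, group=row["group"]
            )
            for h, sess in zip(np.arange(spec.n_sessions_per_day) * 24.0 / spec.n_sessions_per_day, day):
                sess.session_id = f"{row['sample_id']}_{gas}_h{h:04.1f}"
            sessions.extend(day)

    tables = {
        k: simulate_counts(spec, metadata, k, np.random.default_rng(child))
        for k, child in zip(KINGDOMS, ss_counts.spawn(len(KINGDOMS)))
    }
    nutrients = simulate_nutrients(spec)
    truth = GroundTruth(
        true_rate_group={f"{g}|{gas}": v for (g, gas), v in spec.true_rate.items()},
        true_rate_animal=true_animal,
        compositions={
            k: default_community(k)[0].to_dict(orient="index") for k in KINGDOMS
        },
        nutrients=nutrients.to_dict(orient="index"),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_chamber_series(sessions, out / "chamber_series.csv")
        io.write_metadata(metadata, out / "metadata.tsv")
        io.write_nutrients(nutrients, out / "nutrients.tsv")
        for k, table in tables.items():
            io.write_count_table(table, out / f"counts_{k}.tsv", out / f"taxonomy_{k}.tsv")
        truth.to_json(out / "ground_truth.json")
    return sessions, metadata, tables, nutrients, truth
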