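"""Synthetic multi-hospital encounter-data generator.

Emulates the structure of admission/discharge/transfer records from a
network of community hospitals and one academic medical center: hospitals
of a handful to a few dozen NHSN-typed units, per-unit age mixtures,
log-normal lengths of stay (heavy right tail), zero-inflated Elixhauser
comorbidity scores, per-day antibiotic spectrum-rank exposure, and
multi-unit transfer chains.

Four named archetypes cover the qualitatively distinct hospital profiles
the analysis is designed to distinguish:

``uniform_adult``
    flat mixing across adult ages (a general community hospital);
``young_skew``
    age mass concentrated at 20-40 (obstetric-heavy catchment);
``elderly_small``
    a small hospital dominated by elderly patients, containing a small
    age-90 subgroup with roughly 10x the modal length of stay — the
    mechanism that puts a hotspot at (90, 90) in the age mixing matrix
    without that group being numerous;
``academic_pediatric``
    a large academic center with pediatric and neonatal critical-care
    units whose daily antibiotic exposure probabilities are high on both
    the narrow and extended spectrum ranks (combination empirical
    therapy), plus nonzero broad-rank use.

Determinism: a bundle is fully reproducible from its config.  One
pseudo-random stream is seeded per hospital and split deterministically
per unit, so editing one unit's profile leaves other units' draws intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from wardmix.encounter_model import (
    ABX_RANKS,
    AGE_MAX,
    ELIX_MAX,
    AbxExposure,
    Admission,
    EncounterBundle,
    UnitStay,
)

ARCHETYPES = ("uniform_adult", "young_skew", "elderly_small", "academic_pediatric")

_MAX_TRANSFERS = 5  # cap on transfer-chain length


@dataclass(frozen=True)
class AgeComponent:
    """One component of a truncated-normal age mixture.

    ``los_multiplier`` scales the sampled length of stay for patients drawn
    from this component; it is how a long-LOS elderly subgroup is modelled.
    """

    weight: float
    mean: float
    sd: float
    los_multiplier: float = 1.0


@dataclass(frozen=True)
class LosSpec:
    """Log-normal length-of-stay distribution (days), mu/sigma on log scale."""

    mu: float
    sigma: float

    @property
    def mean_days(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)


@dataclass(frozen=True)
class ElixModel:
    """Zero-inflated Poisson over the Elixhauser score, truncated to [0, 16]."""

    p_zero: float
    poisson_mean: float


@dataclass(frozen=True)
class UnitProfile:
    unit_type: str
    bed_pressure: float  # target mean daily census
    los_days: LosSpec
    age_model: tuple[AgeComponent, ...]
    elix_model: ElixModel
    abx_model: dict[str, float]  # per-rank daily exposure probability
    transfer_out_prob: float = 0.0
    sex_probs: tuple[float, float, float] = (0.55, 0.41, 0.04)  # F, M, missing

    def __post_init__(self):
        w = sum(c.weight for c in self.age_model)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"age mixture weights sum to {w}, expected 1")
        for r, p in self.abx_model.items():
            if r not in ABX_RANKS:
                raise ValueError(f"unknown antibiotic rank {r!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"abx probability {p} for {r!r} outside [0,1]")
        if not (0.0 <= self.transfer_out_prob <= 1.0):
            raise ValueError("transfer_out_prob outside [0,1]")
        if self.los_days.mean_days <= 0:
            raise ValueError("length of stay must be positive")

    @property
    def mean_age(self) -> float:
        return sum(c.weight * c.mean for c in self.age_model)


@dataclass(frozen=True)
class HospitalConfig:
    hospital_id: str
    unit_profiles: tuple[UnitProfile, ...]
    n_admissions: int
    window: tuple[date, date]
    seed: int

    def __post_init__(self):
        if self.window[0] > self.window[1]:
            raise ValueError("empty simulation window")
        if self.n_admissions < 0:
            raise ValueError("n_admissions must be nonnegative")
        if len(self.unit_profiles) < 1:
            raise ValueError("at least one unit profile required")

    @property
    def n_units(self) -> int:
        return len(self.unit_profiles)

    def unit_id(self, i: int) -> str:
        return f"{self.hospital_id}-U{i + 1:02d}"


def _ward(unit_type, census, los_mu, los_sigma, ages, elix, abx, transfer=0.15, **kw):
    return UnitProfile(
        unit_type=unit_type,
        bed_pressure=census,
        los_days=LosSpec(los_mu, los_sigma),
        age_model=tuple(ages),
        elix_model=elix,
        abx_model=abx,
        transfer_out_prob=transfer,
        **kw,
    )


_DEFAULT_WINDOW = (date(2017, 1, 1), date(2017, 3, 31))


def archetype_config(name: str, n_admissions: int, seed: int) -> HospitalConfig:
    """Return a fully specified :class:`HospitalConfig` for a named archetype.

    The same ``(name, n_admissions, seed)`` always yields the identical
    config, hence the identical bundle from :func:`generate_bundle`.
    """
    if name not in ARCHETYPES:
        raise ValueError(f"unknown archetype {name!r}; options: {ARCHETYPES}")

    adult_elix = ElixModel(p_zero=0.45, poisson_mean=2.5)
    icu_elix = ElixModel(p_zero=0.15, poisson_mean=4.5)
    young_elix = ElixModel(p_zero=0.75, poisson_mean=1.0)
    peds_elix = ElixModel(p_zero=0.85, poisson_mean=0.6)

    if name == "uniform_adult":
        flat_adult = (
            AgeComponent(0.25, 30, 12),
            AgeComponent(0.25, 45, 12),
            AgeComponent(0.25, 60, 12),
            AgeComponent(0.25, 75, 12),
        )
        units = [
            _ward("adult medical ward", 22, 1.2, 0.6, flat_adult, adult_elix,
                  {"narrow": 0.10, "broad": 0.15, "extended": 0.08, "protected": 0.01}),
            _ward("adult medical ward", 20, 1.2, 0.6, flat_adult, adult_elix,
                  {"narrow": 0.10, "broad": 0.15, "extended": 0.08, "protected": 0.01}),
            _ward("adult surgical ward", 18, 1.1, 0.5, flat_adult, adult_elix,
                  {"narrow": 0.25, "broad": 0.08, "extended": 0.05, "protected": 0.01}),
            _ward("adult critical care", 10, 1.5, 0.7, flat_adult, icu_elix,
                  {"narrow": 0.05, "broad": 0.10, "extended": 0.40, "protected": 0.05},
                  transfer=0.45),
            _ward("telemetry ward", 14, 1.0, 0.5, flat_adult, adult_elix,
                  {"narrow": 0.05, "broad": 0.20, "extended": 0.15, "protected": 0.01}),
            _ward("emergency department", 25, 0.1, 0.3, flat_adult, adult_elix,
                  {"narrow": 0.08, "broad": 0.20, "extended": 0.18, "protected": 0.00},
                  transfer=0.30),
            _ward("24-hour observation", 8, 0.2, 0.3, flat_adult, adult_elix,
                  {"narrow": 0.05, "broad": 0.12, "extended": 0.10, "protected": 0.00}),
            _ward("orthopedic ward", 10, 1.0, 0.4, flat_adult, adult_elix,
                  {"narrow": 0.35, "broad": 0.05, "extended": 0.03, "protected": 0.00}),
        ]
    elif name == "young_skew":
        young = (AgeComponent(0.55, 27, 6), AgeComponent(0.35, 33, 6),
                 AgeComponent(0.10, 45, 10))
        units = [
            _ward("labor and delivery ward", 16, 0.9, 0.4, young, young_elix,
                  {"narrow": 0.40, "broad": 0.04, "extended": 0.02, "protected": 0.00},
                  sex_probs=(0.96, 0.0, 0.04)),
            _ward("postpartum ward", 14, 0.8, 0.4, young, young_elix,
                  {"narrow": 0.30, "broad": 0.03, "extended": 0.02, "protected": 0.00},
                  sex_probs=(0.96, 0.0, 0.04)),
            _ward("adult medical ward", 12, 1.1, 0.5, young, adult_elix,
                  {"narrow": 0.10, "broad": 0.15, "extended": 0.08, "protected": 0.01}),
            _ward("gynecology ward", 8, 0.9, 0.4, young, young_elix,
                  {"narrow": 0.35, "broad": 0.05, "extended": 0.02, "protected": 0.00},
                  sex_probs=(0.96, 0.0, 0.04)),
            _ward("behavioral health ward", 10, 1.6, 0.5, young, young_elix,
                  {"narrow": 0.02, "broad": 0.03, "extended": 0.01, "protected": 0.00}),
            _ward("emergency department", 18, 0.1, 0.3, young, young_elix,
                  {"narrow": 0.08, "broad": 0.18, "extended": 0.15, "protected": 0.00},
                  transfer=0.25),
        ]
    elif name == "elderly_small":
        # ~8% of admissions are age-90 patients whose LOS is 10x the ward's;
        # the modal ages around 72 spread across many single-year bins.
        elderly = (
            AgeComponent(0.92, 72, 8, los_multiplier=1.0),
            AgeComponent(0.08, 90, 0.5, los_multiplier=10.0),
        )
        units = [
            _ward("adult medical ward", 18, 1.2, 0.5, elderly, adult_elix,
                  {"narrow": 0.08, "broad": 0.18, "extended": 0.12, "protected": 0.01}),
            _ward("adult medical ward", 14, 1.2, 0.5, elderly, adult_elix,
                  {"narrow": 0.08, "broad": 0.18, "extended": 0.12, "protected": 0.01}),
            _ward("telemetry ward", 10, 1.0, 0.5, elderly, adult_elix,
                  {"narrow": 0.05, "broad": 0.20, "extended": 0.15, "protected": 0.01}),
            _ward("adult critical care", 6, 1.4, 0.6, elderly, icu_elix,
                  {"narrow": 0.04, "broad": 0.10, "extended": 0.40, "protected": 0.04},
                  transfer=0.40),
            _ward("emergency department", 12, 0.1, 0.3,
                  (AgeComponent(0.6, 55, 18), AgeComponent(0.4, 35, 12)), adult_elix,
                  {"narrow": 0.05, "broad": 0.22, "extended": 0.20, "protected": 0.00},
                  transfer=0.30),
        ]
    else:  # academic_pediatric
        maternal = (AgeComponent(0.85, 28, 5), AgeComponent(0.15, 33, 4))
        infant = (AgeComponent(1.0, 0, 0.4),)
        child = (AgeComponent(0.6, 2, 2), AgeComponent(0.4, 10, 5))
        flat_adult = (
            AgeComponent(0.25, 30, 12),
            AgeComponent(0.25, 45, 12),
            AgeComponent(0.25, 60, 12),
            AgeComponent(0.25, 75, 12),
        )
        # NICU and pediatric units: nonzero narrow, broad AND extended daily
        # probabilities, with narrow+extended dominant (combination therapy).
        nicu_abx = {"narrow": 0.55, "broad": 0.03, "extended": 0.50, "protected": 0.01}
        peds_abx = {"narrow": 0.20, "broad": 0.35, "extended": 0.15, "protected": 0.01}
        units = [
            _ward("neonatal critical care", 12, 2.0, 0.6, infant, peds_elix,
                  nicu_abx, transfer=0.10),
            _ward("well baby nursery", 14, 0.7, 0.3, infant, peds_elix,
                  {"narrow": 0.30, "broad": 0.05, "extended": 0.20, "protected": 0.00}),
            _ward("pediatric medical ward", 12, 1.1, 0.5, child, peds_elix, peds_abx),
            _ward("pediatric critical care", 8, 1.5, 0.6, child,
                  ElixModel(p_zero=0.55, poisson_mean=2.0), peds_abx, transfer=0.25),
            _ward("labor and delivery ward", 16, 0.9, 0.4, maternal, young_elix,
                  {"narrow": 0.40, "broad": 0.04, "extended": 0.02, "protected": 0.00},
                  sex_probs=(0.96, 0.0, 0.04)),
            _ward("postpartum ward", 14, 0.8, 0.4, maternal, young_elix,
                  {"narrow": 0.30, "broad": 0.03, "extended": 0.02, "protected": 0.00},
                  sex_probs=(0.96, 0.0, 0.04)),
            _ward("adult medical ward", 22, 1.2, 0.6, flat_adult, adult_elix,
                  {"narrow": 0.10, "broad": 0.15, "extended": 0.08, "protected": 0.01}),
            _ward("adult surgical ward", 18, 1.1, 0.5, flat_adult, adult_elix,
                  {"narrow": 0.25, "broad": 0.08, "extended": 0.05, "protected": 0.01}),
            _ward("adult critical care", 12, 1.5, 0.7, flat_adult, icu_elix,
                  {"narrow": 0.05, "broad": 0.10, "extended": 0.40, "protected": 0.06},
                  transfer=0.45),
            _ward("surgical cardiothoracic critical care", 8, 1.4, 0.6, flat_adult,
                  icu_elix, nicu_abx, transfer=0.35),
            _ward("emergency department", 28, 0.1, 0.3, flat_adult, adult_elix,
                  {"narrow": 0.08, "broad": 0.25, "extended": 0.22, "protected": 0.00},
                  transfer=0.30),
            _ward("24-hour observation", 8, 0.2, 0.3, flat_adult, adult_elix,
                  {"narrow": 0.05, "broad": 0.12, "extended": 0.10, "protected": 0.00}),
        ]

    return HospitalConfig(
        hospital_id=f"H-{name}",
        unit_profiles=tuple(units),
        n_admissions=n_admissions,
        window=_DEFAULT_WINDOW,
        seed=seed,
    )


def _sample_age(rng: np.random.Generator, comp: AgeComponent) -> int:
    a = rng.normal(comp.mean, comp.sd) if comp.sd > 0 else comp.mean
    return int(min(max(round(a), 0), AGE_MAX))  # top-code at 90


def _sample_elix(rng: np.random.Generator, model: ElixModel) -> int:
    if rng.random() < model.p_zero:
        return 0
    return int(min(rng.poisson(model.poisson_mean), ELIX_MAX))


def _sample_los_days(rng: np.random.Generator, spec: LosSpec, multiplier: float) -> int:
    los = rng.lognormal(spec.mu, spec.sigma) * multiplier
    return max(1, int(round(los)))


def generate_bundle(config: HospitalConfig) -> EncounterBundle:
    """Simulate one hospital's encounter bundle from its config.

    Exactly ``n_admissions`` admissions are produced; each has at least one
    unit stay; transfer chains share the boundary day (stay1 exit equals
    stay2 entry), so a transferred patient appears on both rosters that day.
    Stays that would run past the window end are truncated there.
    """
    start, end = config.window
    n_days = (end - start).days + 1
    n_units = config.n_units

    # Arrivals split across units in proportion to target census over mean
    # LOS (a homogeneous Poisson process per unit, conditioned on the total).
    rates = np.array(
        [
            p.bed_pressure / max(p.los_days.mean_days, 1e-9)
            for p in config.unit_profiles
        ]
    )
    probs = rates / rates.sum()
    hospital_rng = np.random.default_rng([config.seed, 0])
    unit_counts = hospital_rng.multinomial(config.n_admissions, probs)

    admissions: list[Admission] = []
    stays: list[UnitStay] = []
    exposures: list[AbxExposure] = []
    serial = 0

    for u in range(n_units):
        rng = np.random.default_rng([config.seed, u + 1])
        profile = config.unit_profiles[u]
        for _ in range(unit_counts[u]):
            serial += 1
            aid = f"{config.hospital_id}-A{serial:06d}"
            pid = f"{config.hospital_id}-P{serial:06d}"

            comp_idx = rng.choice(
                len(profile.age_model), p=[c.weight for c in profile.age_model]
            )
            comp = profile.age_model[comp_idx]
            age = _sample_age(rng, comp)
            elix = _sample_elix(rng, profile.elix_model)
            sex = ("F", "M", "missing")[
                rng.choice(3, p=np.asarray(profile.sex_probs) / sum(profile.sex_probs))
            ]

            # first stay in the home unit, then a transfer chain
            entry = start + timedelta(days=int(rng.integers(0, n_days)))
            cur_unit = u
            adm_stays: list[UnitStay] = []
            for hop in range(_MAX_TRANSFERS + 1):
                cur_profile = config.unit_profiles[cur_unit]
                los = _sample_los_days(rng, cur_profile.los_days, comp.los_multiplier)
                exit_d = min(entry + timedelta(days=los - 1), end)
                adm_stays.append(
                    UnitStay(
                        admission_id=aid,
                        unit_id=config.unit_id(cur_unit),
                        unit_type=cur_profile.unit_type,
                        entry_date=entry,
                        exit_date=exit_d,
                    )
                )
                if (
                    exit_d >= end
                    or n_units < 2
                    or hop == _MAX_TRANSFERS
                    or rng.random() >= cur_profile.transfer_out_prob
                ):
                    break
                nxt = int(rng.integers(0, n_units - 1))
                nxt = nxt if nxt < cur_unit else nxt + 1  # any other unit
                # a 1-day hop back to a unit left the same day would
                # duplicate a (admission, unit, entry) stay row; stop instead
                if any(
                    s.unit_id == config.unit_id(nxt) and s.entry_date == exit_d
                    for s in adm_stays
                ):
                    break
                cur_unit = nxt
                entry = exit_d  # boundary day shared by both units

            admissions.append(
                Admission(
                    admission_id=aid,
                    patient_id=pid,
                    hospital_id=config.hospital_id,
                    age=age,
                    sex=sex,
                    elixhauser=elix,
                    admit_date=adm_stays[0].entry_date,
                    discharge_date=adm_stays[-1].exit_date,
                )
            )
            stays.extend(adm_stays)

            # daily antibiotic exposure under the profile of the unit
            # occupied that day (transfer boundary days belong to the
            # earlier stay); independent Bernoulli per rank per day
            seen: set[tuple[date, str]] = set()
            for si, stay in enumerate(adm_stays):
                sp = config.unit_profiles[
                    int(stay.unit_id.rsplit("U", 1)[1]) - 1
                ]
                # shared boundary day is owned by the earlier stay
                d = stay.entry_date if si == 0 else stay.entry_date + timedelta(days=1)
                while d <= stay.exit_date:
                    for rank in ABX_RANKS:
                        p = sp.abx_model.get(rank, 0.0)
                        if p > 0 and rng.random() < p and (d, rank) not in seen:
                            seen.add((d, rank))
                            exposures.append(
                                AbxExposure(admission_id=aid, date=d, rank=rank)
                            )
                    d += timedelta(days=1)

    return EncounterBundle(admissions=admissions, stays=stays, exposures=exposures)


def generate_multi(configs) -> EncounterBundle:
    """Concatenate bundles generated from several hospital configs."""
    out = EncounterBundle()
    for cfg in configs:
        b = generate_bundle(cfg)
        out.admissions.extend(b.admissions)
        out.stays.extend(b.stays)
        out.exposures.extend(b.exposures)
    return out


def summarize_bundle(bundle: EncounterBundle) -> pd.DataFrame:
    """Per-hospital summary: counts, median age, % multi-unit admissions."""
    cols = [
        "hospital_id",
        "n_admissions",
        "n_patients",
        "n_units",
        "median_age",
        "pct_multiunit",
    ]
    if not bundle.admissions:
        return pd.DataFrame(columns=cols)
    units_per_adm: dict[str, set[str]] = {}
    for s in bundle.stays:
        units_per_adm.setdefault(s.admission_id, set()).add(s.unit_id)
    rows = []
    for hid in bundle.hospital_ids():
        adms = [a for a in bundle.admissions if a.hospital_id == hid]
        multi = sum(1 for a in adms if len(units_per_adm.get(a.admission_id, set())) >= 2)
        rows.append(
            {
                "hospital_id": hid,
                "n_admissions": len(adms),
                "n_patients": len({a.patient_id for a in adms}),
                "n_units": len(
                    set().union(*(units_per_adm.get(a.admission_id, set()) for a in adms))
                ),
                "median_age": float(np.median([a.age for a in adms])),
                "pct_multiunit": 100.0 * multi / len(adms),
            }
        )
    return pd.DataFrame(rows, columns=cols)


# -- YAML config round-trip -------------------------------------------------

def config_to_dict(config: HospitalConfig) -> dict:
    return {
        "hospital_id": config.hospital_id,
        "n_admissions": config.n_admissions,
        "seed": config.seed,
        "window": [config.window[0].isoformat(), config.window[1].isoformat()],
        "units": [
            {
                "unit_type": p.unit_type,
                "bed_pressure": p.bed_pressure,
                "los_days": {"dist": "lognormal", "mu": p.los_days.mu,
                             "sigma": p.los_days.sigma},
                "age_model": [
                    {"weight": c.weight, "mean": c.mean, "sd": c.sd,
                     "los_multiplier": c.los_multiplier}
                    for c in p.age_model
                ],
                "elix_model": {"p_zero": p.elix_model.p_zero,
                               "poisson_mean": p.elix_model.poisson_mean},
                "abx_model": dict(p.abx_model),
                "transfer_out_prob": p.transfer_out_prob,
                "sex_probs": list(p.sex_probs),
            }
            for p in config.unit_profiles
        ],
    }


def config_from_dict(d: dict) -> HospitalConfig:
    units = tuple(
        UnitProfile(
            unit_type=u["unit_type"],
            bed_pressure=u["bed_pressure"],
            los_days=LosSpec(u["los_days"]["mu"], u["los_days"]["sigma"]),
            age_model=tuple(
                AgeComponent(c["weight"], c["mean"], c["sd"],
                             c.get("los_multiplier", 1.0))
                for c in u["age_model"]
            ),
            elix_model=ElixModel(u["elix_model"]["p_zero"],
                                 u["elix_model"]["poisson_mean"]),
            abx_model=dict(u["abx_model"]),
            transfer_out_prob=u.get("transfer_out_prob", 0.0),
            sex_probs=tuple(u.get("sex_probs", (0.55, 0.41, 0.04))),
        )
        for u in d["units"]
    )
    return HospitalConfig(
        hospital_id=d["hospital_id"],
        unit_profiles=units,
        n_admissions=d["n_admissions"],
        window=(date.fromisoformat(d["window"][0]), date.fromisoformat(d["window"][1])),
        seed=d["seed"],
    )


def load_config(path) -> HospitalConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: HospitalConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
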