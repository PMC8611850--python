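"""Synthetic magnetized water-and-fertilizer measurement generator.

The study system: a water/fertilizer solution passes through (or sits in) a
magnetizer whose field strength is stepped over a 0–450 mT grid in 50 mT
increments, and four physico-chemical properties are measured at each level —
surface tension coefficient sigma (N/m), dynamic viscosity eta (mPa·s),
electrical conductivity EC (µS/cm) and pH.  Measurements exist in two
domains: *static* solution magnetized at rest (plentiful) and *dynamic*
solution magnetized while flowing, as during irrigation (scarce, and shifted
relative to static because the residence time in the field is shorter).

Each property's mean response to the field is modelled as a saturating
exponential

    mean(B) = base + amplitude * (1 - exp(-B / scale)) + roughness(B)

where ``roughness`` is a zero-mean, per-level perturbation that is frozen by
the seed (the same level always receives the same offset within one
dataset), giving the non-smooth, "unstable-sequence" character that real
surface-tension series show.  Replicate scatter on top of the level mean is
additive i.i.d. Gaussian noise.

The study-scale preset reproduces the collected-data bookkeeping: 16 dynamic
and 106 static records per property (64 and 424 in total), distributed as
evenly as possible over the 10 field levels with remainders assigned to the
lowest levels first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROPERTIES",
    "DOMAINS",
    "FIELD_GRID_MT",
    "PropertyMeasurement",
    "MagnetizationCurve",
    "GeneratorConfig",
    "property_response",
    "generate_study_dataset",
    "study_preset",
    "distribute_replicates",
    "records_to_frame",
    "frame_to_records",
    "write_csv",
    "read_csv",
]

PROPERTIES = ("sigma", "eta", "EC", "pH")
DOMAINS = ("static", "dynamic")

#: The study's field-strength grid: 0 to 450 mT in arithmetic steps of 50 mT.
FIELD_GRID_MT: tuple[float, ...] = tuple(float(b) for b in range(0, 451, 50))

CSV_COLUMNS = ["property", "field_mT", "domain", "replicate", "value"]


@dataclass(frozen=True)
class PropertyMeasurement:
    """One instrument reading.

    ``value`` carries the property's units: sigma N/m, eta mPa·s,
    EC µS/cm, pH unitless.
    """

    property: str
    field_mT: float
    domain: str
    replicate: int
    value: float

    def __post_init__(self) -> None:
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.field_mT < 0:
            raise ValueError(f"field strength must be >= 0 mT, got {self.field_mT!r}")
        if self.replicate < 0:
            raise ValueError(f"replicate index must be >= 0, got {self.replicate!r}")


@dataclass(frozen=True)
class MagnetizationCurve:
    """Parametric mean response of one property to the applied field.

    ``base_value`` is the unmagnetized (0 mT) mean; ``response_amplitude``
    is the asymptotic change at saturating field; ``response_scale`` (mT)
    sets how fast saturation is approached; ``roughness_sd`` is the spread
    of the frozen per-level perturbation; ``noise_sd`` the replicate noise.
    """

    property: str
    base_value: float
    response_amplitude: float
    response_scale: float
    roughness_sd: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}")
        if self.response_scale <= 0:
            raise ValueError("response_scale must be a positive field strength (mT)")
        if self.roughness_sd < 0 or self.noise_sd < 0:
            raise ValueError("roughness_sd and noise_sd must be >= 0")


def property_response(curve: MagnetizationCurve, field_mT: float, seed: int) -> float:
    """Mean property value at field strength ``field_mT`` (before replicate noise).

    Deterministic given ``(curve, field_mT, seed)``: the roughness offset for
    a level is drawn from a generator keyed on the seed, the curve parameters
    and the level itself, so the same level always perturbs identically
    within one dataset.
    """
    if field_mT < 0:
        raise ValueError(f"field strength must be >= 0 mT, got {field_mT!r}")
    mean = curve.base_value + curve.response_amplitude * (
        1.0 - np.exp(-field_mT / curve.response_scale)
    )
    if curve.roughness_sd > 0:
        key = np.random.SeedSequence(
            [
                int(seed) % (2**31),
                PROPERTIES.index(curve.property),
                int(round(field_mT * 1000.0)),
                abs(hash((curve.base_value, curve.response_amplitude))) % (2**31),
            ]
        )
        rough = np.random.default_rng(key).normal(0.0, curve.roughness_sd)
        mean += rough
    return float(mean)


def distribute_replicates(total: int, n_levels: int) -> list[int]:
    """Spread ``total`` replicates over ``n_levels`` field levels.

    As even as possible; the remainder goes to the lowest levels first
    (e.g. 106 over 10 levels -> six levels of 11 then four of 10).
    """
    if n_levels <= 0:
        raise ValueError("cannot distribute replicates over zero field levels")
    if total <= 0:
        raise ValueError("replicate total must be positive")
    base, extra = divmod(total, n_levels)
    return [base + (1 if i < extra else 0) for i in range(n_levels)]


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic dataset.

    ``curves`` maps (property, domain) to the mean-response curve and
    ``reps`` to the total number of records for that pair; ``field_levels``
    is the measurement grid and ``seed`` fixes every random draw.
    """

    curves: Mapping[tuple[str, str], MagnetizationCurve]
    reps: Mapping[tuple[str, str], int]
    field_levels: Sequence[float] = FIELD_GRID_MT
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.field_levels) == 0:
            raise ValueError("field_levels must be non-empty")
        for key, n in self.reps.items():
            if key not in self.curves:
                raise ValueError(f"reps given for {key} but no curve defined")
            if n <= 0:
                raise ValueError(f"replicate count for {key} must be positive")


# Study-scale mean-response parameters.  Base values are realistic for a
# dilute fertilizer solution at room temperature (surface tension close to
# water's 0.072 N/m, viscosity ~1 mPa·s, EC ~1200 µS/cm, pH slightly acidic);
# amplitudes are the few-percent changes magnetization treatments typically
# produce, and the dynamic (flowing) domain responds more weakly because the
# solution spends less time in the field.
_STUDY_CURVES: dict[tuple[str, str], MagnetizationCurve] = {
    ("sigma", "static"): MagnetizationCurve("sigma", 0.0720, -0.0040, 150.0, 0.0015, 0.0010),
    ("sigma", "dynamic"): MagnetizationCurve("sigma", 0.0700, -0.0020, 180.0, 0.0015, 0.0010),
    ("eta", "static"): MagnetizationCurve("eta", 1.00, -0.080, 200.0, 0.010, 0.010),
    ("eta", "dynamic"): MagnetizationCurve("eta", 0.97, -0.040, 220.0, 0.010, 0.010),
    ("EC", "static"): MagnetizationCurve("EC", 1200.0, 60.0, 150.0, 5.0, 8.0),
    ("EC", "dynamic"): MagnetizationCurve("EC", 1160.0, 30.0, 180.0, 5.0, 8.0),
    ("pH", "static"): MagnetizationCurve("pH", 6.80, 0.25, 200.0, 0.02, 0.03),
    ("pH", "dynamic"): MagnetizationCurve("pH", 6.72, 0.12, 220.0, 0.02, 0.03),
}

#: Collected-data bookkeeping: records per property and domain.
STUDY_REPS = {"static": 106, "dynamic": 16}


def study_preset(seed: int = 0) -> GeneratorConfig:
    """The study-scale generator configuration.

    Emits 106 static and 16 dynamic records for each of the four properties
    (424 and 64 in total) on the 0–450 mT grid.
    """
    reps = {
        (prop, dom): STUDY_REPS[dom] for prop in PROPERTIES for dom in DOMAINS
    }
    return GeneratorConfig(curves=dict(_STUDY_CURVES), reps=reps, seed=seed)


def generate_study_dataset(config: GeneratorConfig) -> list[PropertyMeasurement]:
    """Generate one dataset.

    For each (property, domain) pair the configured replicate total is
    distributed over the field levels, the level mean is evaluated from the
    magnetization curve, and i.i.d. Gaussian replicate noise (sd =
    ``curve.noise_sd``) is added.  Identical configs (including the seed)
    give identical record lists.  Rows are ordered by (property, domain,
    field level, replicate).
    """
    levels = [float(b) for b in config.field_levels]
    records: list[PropertyMeasurement] = []
    for prop in PROPERTIES:
        for dom in DOMAINS:
            key = (prop, dom)
            if key not in config.reps:
                continue
            curve = config.curves[key]
            counts = distribute_replicates(config.reps[key], len(levels))
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [int(config.seed) % (2**31), PROPERTIES.index(prop), DOMAINS.index(dom)]
                )
            )
            for level, n_rep in zip(levels, counts):
                mean = property_response(curve, level, config.seed)
                noise = rng.normal(0.0, curve.noise_sd, size=n_rep)
                for r in range(n_rep):
                    value = mean + float(noise[r])
                    # physical floors: sigma/eta/EC strictly positive, pH in (0, 14)
                    if prop == "pH":
                        value = float(np.clip(value, 1e-6, 14.0 - 1e-6))
                    else:
                        value = max(value, 1e-9)
                    records.append(
                        PropertyMeasurement(prop, level, dom, r, value)
                    )
    return records


# ---------------------------------------------------------------------------
# CSV round-trip (schema: property,field_mT,domain,replicate,value)

def records_to_frame(records: Iterable[PropertyMeasurement]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            (m.property, m.field_mT, m.domain, m.replicate, m.value)
            for m in records
        ],
        columns=CSV_COLUMNS,
    )
    order = frame.assign(
        _p=frame["property"].map(PROPERTIES.index),
        _d=frame["domain"].map(DOMAINS.index),
    ).sort_values(["_p", "_d", "field_mT", "replicate"], kind="mergesort")
    return order[CSV_COLUMNS].reset_index(drop=True)


def frame_to_records(frame: pd.DataFrame) -> list[PropertyMeasurement]:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns {missing}")
    return [
        PropertyMeasurement(
            str(row.property),
            float(row.field_mT),
            str(row.domain),
            int(row.replicate),
            float(row.value),
        )
        for row in frame.itertuples(index=False)
    ]


def write_csv(records: Iterable[PropertyMeasurement], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_csv(path: str | Path) -> list[PropertyMeasurement]:
    # round_trip parsing: values written by write_csv re-read bit-exactly
    return frame_to_records(
        pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    )


def filter_records(
    records: Iterable[PropertyMeasurement],
    property: str | None = None,
    domain: str | None = None,
) -> list[PropertyMeasurement]:
    """Convenience selector by property and/or domain."""
    out = [
        m
        for m in records
        if (property is None or m.property == property)
        and (domain is None or m.domain == domain)
    ]
    return out
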