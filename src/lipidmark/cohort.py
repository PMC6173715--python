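"""Synthetic two-class serum-lipidomics cohorts.

Generates subjects × markers concentration tables with the statistical
structure the downstream analysis assumes: log-normal-like positive
concentrations, per-marker linear age trends and additive sex offsets on
the raw scale, a minority of markers carrying class effects (most lowered
in patients, a few raised), and an imbalanced patient:control design
(102:301 by default, mirroring a multiple-sclerosis case-control study).

The cohort is exchanged everywhere as a plain :class:`pandas.DataFrame`
with four metadata columns (``subject_id``, ``diagnosis``, ``age``,
``sex``) followed by one non-negative concentration column per marker
(ng/ml). ``diagnosis`` is ``"MS"`` or ``"healthy"``; ``sex`` is ``"m"``
or ``"f"``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSpec",
    "CohortConfig",
    "META_COLUMNS",
    "default_panel",
    "default_config",
    "generate_cohort",
    "marker_columns",
    "diagnosis_vector",
    "write_cohort",
    "read_cohort",
]

#: Leading metadata columns of every cohort table, in order.
META_COLUMNS = ("subject_id", "diagnosis", "age", "sex")

_LIPID_CLASSES = frozenset(
    {
        "ceramide",
        "LPA",
        "sphingolipid",
        "prostaglandin",
        "DHET",
        "HETE",
        "endocannabinoid",
        "pterin",
    }
)


@dataclass(frozen=True)
class MarkerSpec:
    """Generative description of one lipid mediator.

    Parameters
    ----------
    name : str
        Marker name, unique within a panel.
    lipid_class : str
        One of ceramide, LPA, sphingolipid, prostaglandin, DHET, HETE,
        endocannabinoid, pterin.
    log_mean, log_sd : float
        Mean and SD (log ng/ml) of the healthy-group log concentration.
    age_slope : float
        Linear age trend, ng/ml per year, added on the raw scale
        relative to the cohort minimum age.
    sex_offset : float
        Additive male − female shift, ng/ml, added to male subjects.
    class_effect : float
        Signed shift of ``log_mean`` applied to the patient group;
        0 for uninformative markers.
    """

    name: str
    lipid_class: str
    log_mean: float
    log_sd: float
    age_slope: float = 0.0
    sex_offset: float = 0.0
    class_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError(f"log_sd must be > 0 for marker {self.name!r}")
        if self.lipid_class not in _LIPID_CLASSES:
            raise ValueError(
                f"unknown lipid_class {self.lipid_class!r} for marker {self.name!r}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic case-control cohort."""

    n_patients: int = 102
    n_controls: int = 301
    markers: tuple[MarkerSpec, ...] = field(default_factory=tuple)
    age_range_patients: tuple[float, float] = (18.2, 62.8)
    age_range_controls: tuple[float, float] = (18.0, 53.2)
    male_fraction_patients: float = 31 / 102
    male_fraction_controls: float = 118 / 301
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if not self.markers:
            raise ValueError("marker panel must not be empty")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique within a panel")
        for frac in (self.male_fraction_patients, self.male_fraction_controls):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("male fractions must lie in [0, 1]")
        for lo, hi in (self.age_range_patients, self.age_range_controls):
            if not (18.0 <= lo <= hi <= 120.0):
                raise ValueError("age intervals must lie within [18, 120]")


def _uninformative(name: str, lipid_class: str, log_mean: float, log_sd: float) -> MarkerSpec:
    return MarkerSpec(name, lipid_class, log_mean, log_sd)


def default_panel() -> tuple[MarkerSpec, ...]:
    """The default 43-marker panel.

    Eight markers are informative for the patient class: six lowered
    (GluCerC16, HETE15S, LPA20:4, biopterin, OEA, PEA) and two raised
    (LacCerC24:1, C16Sphinganin). GluCerC16 carries the strongest shift
    (−2.5 log-SD, matching a marker that discriminates on its own at
    >90% accuracy); the other seven carry ±1.25 log-SD. The informative
    markers also carry the published age slopes and male−female median
    offsets, so the confound-correction stage has real work to do.
    """
    informative = [
        MarkerSpec("GluCerC16", "ceramide", 5.9, 0.40, -1.6263, -10.2439, -1.000),
        MarkerSpec("HETE15S", "HETE", 2.5, 0.50, -0.0749, 0.3065, -0.625),
        MarkerSpec("LPA20:4", "LPA", 4.6, 0.50, 0.5206, -9.8383, -0.625),
        MarkerSpec("biopterin", "pterin", 1.5, 0.40, -0.0184, 0.4211, -0.500),
        MarkerSpec("OEA", "endocannabinoid", 0.7, 0.35, 0.0063, 0.32, -0.4375),
        MarkerSpec("LacCerC24:1", "ceramide", 9.2, 0.30, 19.0459, -329.1148, 0.375),
        MarkerSpec("PEA", "endocannabinoid", 0.7, 0.35, -0.0136, 0.1177, -0.4375),
        MarkerSpec("C16Sphinganin", "sphingolipid", 4.5, 0.40, 1.406441, -0.1384429, 0.500),
    ]
    noise = [
        _uninformative("Cer16:0", "ceramide", 5.5, 0.45),
        _uninformative("Cer18:0", "ceramide", 4.1, 0.50),
        _uninformative("Cer18:1", "ceramide", 3.2, 0.50),
        _uninformative("Cer20:0", "ceramide", 4.3, 0.45),
        _uninformative("Cer24:0", "ceramide", 6.7, 0.40),
        _uninformative("Cer24:1", "ceramide", 6.2, 0.40),
        _uninformative("GluCerC24:1", "ceramide", 6.0, 0.45),
        _uninformative("LacCerC16", "ceramide", 7.3, 0.35),
        _uninformative("LacCerC24", "ceramide", 7.8, 0.35),
        _uninformative("LPA16:0", "LPA", 4.2, 0.50),
        _uninformative("LPA18:0", "LPA", 3.6, 0.50),
        _uninformative("LPA18:1", "LPA", 3.4, 0.55),
        _uninformative("LPA18:2", "LPA", 4.4, 0.55),
        _uninformative("LPA18:3", "LPA", 2.8, 0.55),
        _uninformative("sphinganine", "sphingolipid", 2.9, 0.45),
        _uninformative("sphingosine", "sphingolipid", 3.3, 0.45),
        _uninformative("S1P", "sphingolipid", 5.8, 0.35),
        _uninformative("SA1P", "sphingolipid", 4.9, 0.40),
        _uninformative("C18Sphinganin", "sphingolipid", 3.8, 0.45),
        _uninformative("C24Sphinganin", "sphingolipid", 4.7, 0.45),
        _uninformative("C24:1Sphinganin", "sphingolipid", 4.9, 0.45),
        _uninformative("PGD2", "prostaglandin", 0.4, 0.60),
        _uninformative("PGE2", "prostaglandin", 0.6, 0.60),
        _uninformative("PGF1a", "prostaglandin", 0.3, 0.60),
        _uninformative("PGF2a", "prostaglandin", 0.5, 0.60),
        _uninformative("TXB2", "prostaglandin", 1.2, 0.60),
        _uninformative("DHET5.6", "DHET", 0.8, 0.55),
        _uninformative("DHET11.12", "DHET", 0.9, 0.50),
        _uninformative("DHET14.15", "DHET", 1.0, 0.50),
        _uninformative("HETE5S", "HETE", 1.4, 0.55),
        _uninformative("HETE12S", "HETE", 2.3, 0.55),
        _uninformative("HETE20S", "HETE", 1.0, 0.55),
        _uninformative("AEA", "endocannabinoid", 0.2, 0.45),
        _uninformative("2AG", "endocannabinoid", 1.6, 0.55),
        _uninformative("neopterin", "pterin", 0.8, 0.40),
    ]
    return tuple(informative + noise)


#: Names of the informative markers of the default panel and the sign of
#: their planted class effect (+1 raised in patients, −1 lowered).
DEFAULT_INFORMATIVE: dict[str, int] = {
    "GluCerC16": -1,
    "HETE15S": -1,
    "LPA20:4": -1,
    "biopterin": -1,
    "OEA": -1,
    "LacCerC24:1": 1,
    "PEA": -1,
    "C16Sphinganin": 1,
}


def default_config(seed: int = 0) -> CohortConfig:
    """Default 102-patient / 301-control design on the 43-marker panel."""
    return CohortConfig(markers=default_panel(), seed=seed)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one cohort table from a :class:`CohortConfig`.

    Per subject and marker the concentration is
    ``exp(Normal(log_mean + class_effect·[patient], log_sd))
    + age_slope·(age − 18) + sex_offset·[male]``, clamped at 0 (assay
    floor). Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients + config.n_controls
    diagnosis = np.array(["MS"] * config.n_patients + ["healthy"] * config.n_controls)

    ages = np.empty(n)
    ages[: config.n_patients] = rng.uniform(*config.age_range_patients, config.n_patients)
    ages[config.n_patients:] = rng.uniform(*config.age_range_controls, config.n_controls)

    # exact sex counts per group: round-half-up of fraction × group size
    sex = np.empty(n, dtype="<U1")
    for sl, frac, size in (
        (slice(0, config.n_patients), config.male_fraction_patients, config.n_patients),
        (slice(config.n_patients, n), config.male_fraction_controls, config.n_controls),
    ):
        n_male = int(np.floor(frac * size + 0.5))
        codes = np.array(["m"] * n_male + ["f"] * (size - n_male))
        rng.shuffle(codes)
        sex[sl] = codes

    is_patient = diagnosis == "MS"
    is_male = sex == "m"
    columns: dict[str, np.ndarray] = {}
    n_clamped = 0
    for spec in config.markers:
        mu = np.where(is_patient, spec.log_mean + spec.class_effect, spec.log_mean)
        conc = np.exp(rng.normal(mu, spec.log_sd))
        conc = conc + spec.age_slope * (ages - 18.0) + np.where(is_male, spec.sex_offset, 0.0)
        n_clamped += int((conc < 0).sum())
        columns[spec.name] = np.clip(conc, 0.0, None)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "diagnosis": diagnosis,
            "age": ages,
            "sex": sex,
            **columns,
        }
    )
    table.attrs["n_clamped"] = n_clamped
    return table


def marker_columns(cohort: pd.DataFrame) -> list[str]:
    """Names of the concentration columns of a cohort table."""
    return [c for c in cohort.columns if c not in META_COLUMNS]


def diagnosis_vector(cohort: pd.DataFrame) -> np.ndarray:
    """Binary labels: 1 for patients (MS), 0 for healthy controls."""
    return (cohort["diagnosis"].to_numpy() == "MS").astype(int)


def write_cohort(cohort: pd.DataFrame, destination) -> None:
    """Write a cohort table as CSV (UTF-8, '.' decimal separator)."""
    cohort.to_csv(destination, index=False, float_format="%.17g")


class CohortParseError(ValueError):
    """Raised when a cohort CSV violates the documented dialect."""


def read_cohort(source) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Raises
    ------
    CohortParseError
        On a malformed header, an unknown diagnosis or sex code, a
        missing metadata value, or a negative concentration; the message
        names the offending row and column.
    """
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(str(source))
    table = pd.read_csv(source)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise CohortParseError(f"malformed header: missing column(s) {missing}")
    if list(table.columns[: len(META_COLUMNS)]) != list(META_COLUMNS):
        raise CohortParseError(
            f"malformed header: first columns must be {list(META_COLUMNS)}"
        )
    markers = marker_columns(table)
    for col in ("diagnosis", "age", "sex"):
        if table[col].isna().any():
            row = int(table[col].isna().idxmax())
            raise CohortParseError(f"missing {col} in row {row}")
    bad_dx = ~table["diagnosis"].isin(["MS", "healthy"])
    if bad_dx.any():
        row = int(bad_dx.idxmax())
        raise CohortParseError(
            f"unknown diagnosis {table.loc[row, 'diagnosis']!r} in row {row}"
        )
    bad_sex = ~table["sex"].isin(["m", "f"])
    if bad_sex.any():
        row = int(bad_sex.idxmax())
        raise CohortParseError(f"unknown sex code {table.loc[row, 'sex']!r} in row {row}")
    for col in markers:
        values = pd.to_numeric(table[col], errors="coerce")
        if values.isna().any() and not table[col].isna().any():
            row = int(values.isna().idxmax())
            raise CohortParseError(f"non-numeric concentration in row {row}, column {col!r}")
        if (values < 0).any():
            row = int((values < 0).idxmax())
            raise CohortParseError(f"negative concentration in row {row}, column {col!r}")
        table[col] = values.astype(float)
    table["age"] = table["age"].astype(float)
    return table


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
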