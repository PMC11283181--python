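"""Synthetic obstetrics cohort with known structure and injectable defects.

The generator emulates the *shape* of a multi-hospital delivery-episode
export: ~27 columns mixing counts (parity, prior C-sections), continuous
measures (age, BMI, gestational ages, serial ultrasound fetal weight
estimates), categoricals (Robson group, delivery type, blood group), a
date-of-birth column, hospital-level baseline shifts, and per-column
missingness up to far beyond 80% (the vacuum-delivery count, to exercise
the high-missingness drop rule).  Key engineered dependencies:

* the Robson group is derived *deterministically* from parity, previous
  C-section, plurality, presentation, gestational age and labor onset via
  the standard 10-group classification — a learnable backbone for the
  Bayesian network;
* delivery type is strongly driven by the Robson group, and a pre-labor
  cesarean onset forces a cesarean delivery (so a eutocic delivery in that
  context is impossible in clean data — the designed contextual defect);
* serial fetal weight estimates are strictly increasing by construction;
* the blood group is independent of everything — the designed chance-level
  cross-validation control.

Every fully observed clean row passes all 17 default rules by construction.
All randomness flows from one seed through a named generator per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records_io import ColumnSpec, DataDictionary, RecordTable, normalize_table

#: Default marginal (MCAR) missingness per column, loosely following the
#: habitual-gap pattern of multi-hospital obstetric exports.  The
#: vacuum-delivery count and the Bishop score are structurally missing on
#: top of this (observed only for vacuum deliveries / induced labors).
DEFAULT_MISSINGNESS: dict[str, float] = {
    "maternal_dob": 0.02,
    "maternal_age": 0.002,
    "maternal_height": 0.12,
    "maternal_weight": 0.14,
    "bmi": 0.15,
    "parity": 0.30,
    "n_pregnancies": 0.002,
    "n_prev_eutocic": 0.45,
    "n_prev_csections": 0.55,
    "n_prenatal_visits": 0.16,
    "gestational_age_admission": 0.01,
    "gestational_age_delivery": 0.002,
    "pregnancy_type": 0.12,
    "fetal_position_admission": 0.60,
    "fetal_position_delivery": 0.002,
    "labor_onset": 0.05,
    "robson_group": 0.055,
    "delivery_type": 0.0,
    "blood_group": 0.003,
    "efw_week25": 0.35,
    "efw_week30": 0.30,
    "efw_week35": 0.25,
    "birth_weight": 0.01,
}

DELIVERY_TYPES = ("eutocic", "vacuum", "forceps", "cesarean")
POSITIONS = ("cephalic", "breech", "transverse")
ONSETS = ("spontaneous", "induced", "prelabor_cesarean")
BLOOD_GROUPS = ("O+", "A+", "B+", "AB+", "O-", "A-", "B-", "AB-")
BLOOD_PROBS = (0.36, 0.34, 0.08, 0.03, 0.09, 0.07, 0.02, 0.01)

DEFECT_KINDS = (
    "made_missing",
    "valueset_violation",
    "range_violation",
    "format_violation",
    "contextual_outlier",
    "global_outlier",
)


def default_dictionary() -> DataDictionary:
    """Data dictionary of the synthetic obstetrics cohort."""
    c = ColumnSpec
    return DataDictionary((
        c("record_id", "identifier"),
        c("hospital_id", "categorical",
          value_set=tuple(f"H{i}" for i in range(1, 10))),
        c("maternal_dob", "date", date_format="d/m/Y"),
        c("maternal_age", "continuous", unit="years"),
        c("maternal_height", "continuous", unit="cm"),
        c("maternal_weight", "continuous", unit="kg"),
        c("bmi", "continuous", unit="kg/m^2"),
        c("parity", "count"),
        c("n_pregnancies", "count"),
        c("n_prev_eutocic", "count"),
        c("n_prev_csections", "count"),
        c("n_prenatal_visits", "count"),
        c("gestational_age_admission", "continuous", unit="weeks"),
        c("gestational_age_delivery", "continuous", unit="weeks"),
        c("pregnancy_type", "categorical", value_set=("single", "multiple")),
        c("fetal_position_admission", "categorical", value_set=POSITIONS),
        c("fetal_position_delivery", "categorical", value_set=POSITIONS),
        c("labor_onset", "categorical", value_set=ONSETS),
        c("robson_group", "categorical",
          value_set=tuple(str(i) for i in range(1, 11))),
        c("delivery_type", "categorical", value_set=DELIVERY_TYPES),
        c("bishop_score", "count"),
        c("blood_group", "categorical", value_set=BLOOD_GROUPS),
        c("efw_week25", "continuous", unit="g"),
        c("efw_week30", "continuous", unit="g"),
        c("efw_week35", "continuous", unit="g"),
        c("birth_weight", "continuous", unit="g"),
        c("n_deliveries_vacuum", "count"),
    ))


@dataclass
class CohortSpec:
    n: int = 10_000
    seed: int = 0
    n_hospitals: int = 9
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 1 <= self.n_hospitals <= 9:
            raise ValueError("n_hospitals must be in 1..9")
        for col, r in self.missingness.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {col!r} not in [0,1]")


def _rng(spec_seed: int, name: str) -> np.random.Generator:
    """Named per-column generator so edits to one column leave others stable."""
    tag = sum(ord(ch) * (i + 1) for i, ch in enumerate(name)) % (2**16)
    return np.random.default_rng([spec_seed % (2**31), tag])


def robson_group(
    parity: int, prev_cs: int, multiple: bool, presentation: str,
    ga_delivery: float, onset: str,
) -> int:
    """Standard 10-group Robson classification of a delivery."""
    if multiple:
        return 8
    if presentation == "transverse":
        return 9
    if presentation == "breech":
        return 6 if parity == 0 else 7
    if ga_delivery < 37:
        return 10
    if prev_cs >= 1:
        return 5
    if parity == 0:
        return 1 if onset == "spontaneous" else 2
    return 3 if onset == "spontaneous" else 4


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# delivery-type distribution per Robson group: (eutocic, vacuum, forceps, cesarean)
_DELIVERY_PROBS = {
    1: (0.62, 0.20, 0.05, 0.13),
    2: (0.45, 0.20, 0.05, 0.30),
    3: (0.82, 0.08, 0.02, 0.08),
    4: (0.65, 0.10, 0.03, 0.22),
    5: (0.20, 0.05, 0.01, 0.74),
    6: (0.06, 0.01, 0.01, 0.92),
    7: (0.12, 0.02, 0.01, 0.85),
    8: (0.15, 0.04, 0.01, 0.80),
    9: (0.00, 0.00, 0.00, 1.00),
    10: (0.55, 0.08, 0.02, 0.35),
}


def generate_cohort(spec: CohortSpec) -> RecordTable:
    """Deterministic (per seed) clean cohort; see module docstring."""
    n = spec.n
    dictionary = default_dictionary()

    hosp_rng = _rng(spec.seed, "hospital_id")
    hospitals = [f"H{i}" for i in range(1, spec.n_hospitals + 1)]
    w = hosp_rng.dirichlet(np.full(spec.n_hospitals, 4.0))
    hospital = hosp_rng.choice(hospitals, size=n, p=w)
    h_index = np.array([hospitals.index(h) for h in hospital])
    age_shift = hosp_rng.normal(0.0, 1.2, size=spec.n_hospitals)
    bmi_shift = hosp_rng.normal(0.0, 0.8, size=spec.n_hospitals)

    age = _truncnorm(_rng(spec.seed, "maternal_age"), 30.5, 5.4, 16, 48, n)
    age += age_shift[h_index]
    age = np.clip(age, 16, 48).round(1)

    dob_rng = _rng(spec.seed, "maternal_dob")
    day = dob_rng.integers(1, 29, size=n)
    month = dob_rng.integers(1, 13, size=n)
    birth_year = (2020 - age).astype(int)
    dob = [f"{d}/{m}/{y}" for d, m, y in zip(day, month, birth_year)]

    height = _truncnorm(_rng(spec.seed, "maternal_height"), 163.0, 6.5, 142, 192, n).round(1)
    bmi = _truncnorm(_rng(spec.seed, "bmi"), 24.5, 4.0, 16, 45, n)
    bmi += 0.3 * bmi_shift[h_index]
    bmi = np.clip(bmi, 16, 45)
    weight = (bmi * (height / 100.0) ** 2).round(1)
    bmi = (weight / (height / 100.0) ** 2).round(1)  # keep columns exactly consistent

    par_rng = _rng(spec.seed, "parity")
    parity = np.minimum(par_rng.poisson(0.9, size=n), 8)
    prev_cs = _rng(spec.seed, "n_prev_csections").binomial(parity, 0.18)
    prev_eut = _rng(spec.seed, "n_prev_eutocic").binomial(
        np.maximum(parity - prev_cs, 0), 0.85
    )
    n_pregnancies = parity + 1 + _rng(spec.seed, "n_pregnancies").poisson(0.25, size=n)

    multiple = _rng(spec.seed, "pregnancy_type").random(n) < 0.02
    pregnancy_type = np.where(multiple, "multiple", "single")

    ga_rng = _rng(spec.seed, "gestational_age_delivery")
    ga_delivery = _truncnorm(ga_rng, 39.1, 1.9, 22, 43, n)
    ga_delivery = np.clip(ga_delivery - 1.4 * multiple, 22, 43).round(1)
    ga_admission = np.clip(
        ga_delivery - np.abs(_rng(spec.seed, "gestational_age_admission").normal(0.0, 0.3, n)),
        20, 44,
    ).round(1)

    pos_rng = _rng(spec.seed, "fetal_position_admission")
    term = ga_delivery >= 37
    u = pos_rng.random(n)
    pos_adm = np.where(
        term,
        np.select([u < 0.955, u < 0.99], ["cephalic", "breech"], "transverse"),
        np.select([u < 0.85, u < 0.97], ["cephalic", "breech"], "transverse"),
    )
    pd_rng = _rng(spec.seed, "fetal_position_delivery")
    keep = pd_rng.random(n) < 0.97
    pos_del = np.where(keep, pos_adm, "cephalic")

    on_rng = _rng(spec.seed, "labor_onset")
    u = on_rng.random(n)
    onset = np.select([u < 0.58, u < 0.86], ["spontaneous", "induced"], "prelabor_cesarean")
    # previous cesarean pushes toward a planned cesarean
    u2 = on_rng.random(n)
    redo = (prev_cs >= 1) & (u2 < 0.35)
    onset = np.where(redo, "prelabor_cesarean", onset)

    robson = np.array([
        str(robson_group(int(p), int(c), bool(m), str(pa), float(g), str(o)))
        for p, c, m, pa, g, o in zip(parity, prev_cs, multiple, pos_del, ga_delivery, onset)
    ])

    del_rng = _rng(spec.seed, "delivery_type")
    delivery = np.empty(n, dtype=object)
    for g, probs in _DELIVERY_PROBS.items():
        mask = robson == str(g)
        k = int(mask.sum())
        if k:
            delivery[mask] = del_rng.choice(DELIVERY_TYPES, size=k, p=probs)
    delivery[onset == "prelabor_cesarean"] = "cesarean"  # no labor, no vaginal delivery

    bishop_rng = _rng(spec.seed, "bishop_score")
    bishop = bishop_rng.binomial(13, 0.45, size=n).astype(float)
    bishop[onset != "induced"] = np.nan  # scored before induction only

    blood = _rng(spec.seed, "blood_group").choice(BLOOD_GROUPS, size=n, p=BLOOD_PROBS)

    visits_rng = _rng(spec.seed, "n_prenatal_visits")
    visits = visits_rng.poisson(np.where(ga_delivery < 34, 6.0, 8.0))

    efw_rng = _rng(spec.seed, "efw_week25")
    growth = efw_rng.normal(1.0, 0.07, size=n)
    efw25 = (660 * growth + efw_rng.normal(0, 25, n)).round()
    efw30 = np.maximum(1320 * growth + efw_rng.normal(0, 45, n), efw25 + 50).round()
    efw35 = np.maximum(2380 * growth + efw_rng.normal(0, 70, n), efw30 + 50).round()

    bw_rng = _rng(spec.seed, "birth_weight")
    bw = (3450 - 165 * (40 - ga_delivery)) * growth + bw_rng.normal(0, 120, n)
    bw = np.maximum(bw * np.where(multiple, 0.85, 1.0), 500).round()

    vac_rng = _rng(spec.seed, "n_deliveries_vacuum")
    vacuum = np.where(delivery == "vacuum", 1.0 + vac_rng.poisson(0.08, n), np.nan)

    df = pd.DataFrame({
        "record_id": [f"R{i:06d}" for i in range(n)],
        "hospital_id": hospital,
        "maternal_dob": dob,
        "maternal_age": age,
        "maternal_height": height,
        "maternal_weight": weight,
        "bmi": bmi,
        "parity": parity.astype(float),
        "n_pregnancies": n_pregnancies.astype(float),
        "n_prev_eutocic": prev_eut.astype(float),
        "n_prev_csections": prev_cs.astype(float),
        "n_prenatal_visits": visits.astype(float),
        "gestational_age_admission": ga_admission,
        "gestational_age_delivery": ga_delivery,
        "pregnancy_type": pregnancy_type,
        "fetal_position_admission": pos_adm,
        "fetal_position_delivery": pos_del,
        "labor_onset": onset,
        "robson_group": robson,
        "delivery_type": delivery,
        "bishop_score": bishop,
        "blood_group": blood,
        "efw_week25": efw25,
        "efw_week30": efw30,
        "efw_week35": efw35,
        "birth_weight": bw,
    })
    df["n_deliveries_vacuum"] = vacuum
    df = df[default_dictionary().names]

    # marginal missingness on top of the structural gaps
    for col, rate in spec.missingness.items():
        if rate <= 0 or col not in df.columns:
            continue
        m_rng = _rng(spec.seed, f"missing:{col}")
        hole = m_rng.random(n) < rate
        df.loc[hole, col] = np.nan

    return normalize_table(df, dictionary, provenance=f"synthetic(seed={spec.seed}, n={n})")


# ---------------------------------------------------------------------------
# defect injection


@dataclass
class DefectMask:
    """Per-cell defect kinds; 'none' everywhere except injected cells."""

    kinds: pd.DataFrame  # str cells

    def defective_rows(self) -> np.ndarray:
        return (self.kinds.to_numpy() != "none").any(axis=1)

    def cells_of_kind(self, kind: str) -> list[tuple[int, str]]:
        out = []
        arr = self.kinds.to_numpy()
        for j, col in enumerate(self.kinds.columns):
            for i in np.nonzero(arr[:, j] == kind)[0]:
                out.append((int(i), col))
        return out


_VALUESET_DEFECTS = {
    "robson_group": "11",
    "blood_group": "XX",
    "delivery_type": "unknown_code",
}
_RANGE_DEFECTS = {
    "gestational_age_delivery": (45.0, 50.0),
    "maternal_weight": (260.0, 400.0),
    "bmi": (75.0, 120.0),
    "maternal_age": (61.0, 80.0),
}
_GLOBAL_OUTLIER_COLUMNS = ("birth_weight", "n_prenatal_visits", "maternal_height")


def _contextual_eligible(df: pd.DataFrame) -> np.ndarray:
    """Rows where a eutocic delivery is impossible in clean data."""
    return (
        (df["delivery_type"] == "cesarean")
        & ((df["robson_group"] == "9") | (df["labor_onset"] == "prelabor_cesarean"))
    ).to_numpy()


def _apply_defect(df: pd.DataFrame, kind: str, i: int, col: str, rng) -> bool:
    if kind == "made_missing":
        df.iat[i, df.columns.get_loc(col)] = np.nan
    elif kind == "valueset_violation":
        df.iat[i, df.columns.get_loc(col)] = _VALUESET_DEFECTS[col]
    elif kind == "range_violation":
        lo, hi = _RANGE_DEFECTS[col]
        df.iat[i, df.columns.get_loc(col)] = round(float(rng.uniform(lo, hi)), 1)
    elif kind == "format_violation":
        raw = str(df.iat[i, df.columns.get_loc(col)])
        if raw.count("/") != 2:
            return False
        d, m, y = raw.split("/")
        df.iat[i, df.columns.get_loc(col)] = f"{y}-{int(m):02d}-{int(d):02d}"
    elif kind == "contextual_outlier":
        df.iat[i, df.columns.get_loc(col)] = "eutocic"
    else:
        raise ValueError(kind)
    return True


def _global_outlier_value(obs: np.ndarray, rng, integer: bool) -> float:
    q1, q3 = np.quantile(obs, [0.25, 0.75])
    iqr = q3 - q1
    v = q3 + 3 * iqr + (3 + rng.random() * 3) * max(iqr, 0.05 * abs(q3), 1.0)
    return float(round(v)) if integer else round(float(v), 1)


def _kind_cells(df: pd.DataFrame, null_mask: pd.DataFrame, kind: str) -> list[tuple[int, str]]:
    """Eligible (row, column) cells for one defect kind."""
    cells: list[tuple[int, str]] = []
    if kind == "made_missing":
        for col in df.columns:
            if col == "record_id":
                continue
            for i in np.nonzero(~null_mask[col].to_numpy())[0]:
                cells.append((int(i), col))
    elif kind == "valueset_violation":
        for col in _VALUESET_DEFECTS:
            for i in np.nonzero(~null_mask[col].to_numpy())[0]:
                cells.append((int(i), col))
    elif kind == "range_violation":
        for col in _RANGE_DEFECTS:
            for i in np.nonzero(~null_mask[col].to_numpy())[0]:
                cells.append((int(i), col))
    elif kind == "format_violation":
        for i in np.nonzero(~null_mask["maternal_dob"].to_numpy())[0]:
            cells.append((int(i), "maternal_dob"))
    elif kind == "contextual_outlier":
        elig = _contextual_eligible(df) & ~null_mask["delivery_type"].to_numpy()
        for i in np.nonzero(elig)[0]:
            cells.append((int(i), "delivery_type"))
    elif kind == "global_outlier":
        for col in _GLOBAL_OUTLIER_COLUMNS:
            for i in np.nonzero(~null_mask[col].to_numpy())[0]:
                cells.append((int(i), col))
    else:
        raise ValueError(f"unknown defect kind {kind!r}")
    return cells


def inject_defects(
    table: RecordTable, rates: dict[str, float], seed: int = 0
) -> tuple[RecordTable, DefectMask]:
    """Independently corrupt eligible cells of each defect kind at the given rate."""
    for k, r in rates.items():
        if k not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {k!r}")
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate for {k!r} not in [0,1]")
    df = table.df.copy()
    null0 = table.null_mask()
    mask = pd.DataFrame("none", index=df.index, columns=df.columns)
    global_obs = {
        col: table.numeric_values(col).dropna().to_numpy() for col in _GLOBAL_OUTLIER_COLUMNS
    }
    for kind in DEFECT_KINDS:
        rate = rates.get(kind, 0.0)
        if rate <= 0:
            continue
        rng = np.random.default_rng([seed % (2**31), DEFECT_KINDS.index(kind)])
        for i, col in _kind_cells(df, null0, kind):
            if rng.random() >= rate:
                continue
            if mask.iat[i, mask.columns.get_loc(col)] != "none":
                continue  # one defect per cell
            if kind == "global_outlier":
                spec = table.dictionary[col]
                df.iat[i, df.columns.get_loc(col)] = _global_outlier_value(
                    global_obs[col], rng, spec.kind == "count"
                )
                applied = True
            else:
                applied = _apply_defect(df, kind, i, col, rng)
            if applied:
                mask.iat[i, mask.columns.get_loc(col)] = kind
    corrupted = normalize_table(df, table.dictionary, provenance=table.provenance + "+defects")
    return corrupted, DefectMask(mask)


def inject_row_defects(
    table: RecordTable,
    row_fraction: float = 0.1,
    cells_per_row: int = 3,
    seed: int = 0,
    kinds: tuple[str, ...] = DEFECT_KINDS,
) -> tuple[RecordTable, DefectMask]:
    """Corrupt a fixed fraction of rows, several cells each (mixed kinds).

    The row-level ground truth this produces is the synthetic stand-in for a
    clinician labelling whole records as bad quality.
    """
    rng = np.random.default_rng(seed % (2**31))
    n = len(table)
    bad_rows = rng.choice(n, size=max(1, int(round(row_fraction * n))), replace=False)
    df = table.df.copy()
    null0 = table.null_mask()
    mask = pd.DataFrame("none", index=df.index, columns=df.columns)
    global_obs = {
        col: table.numeric_values(col).dropna().to_numpy() for col in _GLOBAL_OUTLIER_COLUMNS
    }
    by_kind = {k: {} for k in kinds}
    for k in kinds:
        for i, col in _kind_cells(df, null0, k):
            by_kind[k].setdefault(i, []).append(col)
    for i in sorted(bad_rows.tolist()):
        applied = 0
        order = list(rng.permutation(list(kinds)))
        for kind in order + list(kinds):
            if applied >= cells_per_row:
                break
            cols = [
                c for c in by_kind[kind].get(i, [])
                if mask.iat[i, mask.columns.get_loc(c)] == "none"
            ]
            if not cols:
                continue
            col = cols[int(rng.integers(len(cols)))]
            if kind == "global_outlier":
                spec = table.dictionary[col]
                df.iat[i, df.columns.get_loc(col)] = _global_outlier_value(
                    global_obs[col], rng, spec.kind == "count"
                )
                ok = True
            else:
                ok = _apply_defect(df, kind, i, col, rng)
            if ok:
                mask.iat[i, mask.columns.get_loc(col)] = kind
                applied += 1
    corrupted = normalize_table(df, table.dictionary, provenance=table.provenance + "+defects")
    return corrupted, DefectMask(mask)
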