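"""Synthetic spontaneous-report corpora with known ground truth.

The generator emits the same six ``$``-delimited tables a FAERS quarterly
release contains (DEMO, DRUG, REAC, OUTC, INDI, THER) for a corpus whose
statistical structure is exactly the one 2x2 disproportionality assumes:
each report samples a drug set from marginal probabilities, then samples
Preferred-Term mentions independently with probability
``base_rate(pt) * rr(drug, pt)`` (capped at 1), where ``rr`` is the true
relative risk — 1 everywhere except for planted associations.  Demographic
mixes default to the composition reported for a real niraparib cohort
(78.55% female, 77.43% consumer reporters, mostly US reports, receipt years
2017-2021) so the descriptive and sensitivity stages run under realistic
conditions.

Every report is guaranteed at least one event row: reports whose Bernoulli
draws all come up empty receive the designated *filler* PT ("Drug
ineffective", itself a very common FAERS term).  This keeps the configured
vocabulary rates exactly Bernoulli — only the filler term's empirical rate
exceeds its configured one.

Case-version duplication is injected at a configurable rate: a duplicated
case appears twice in DEMO (and DRUG/REAC) under two primaryids, the stale
version carrying an earlier FDA receipt date and smaller version number, so
deduplication must recover exactly the configured number of cases.

A single seeded NumPy generator drives everything; identical seed + config
give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import datetime
import io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import faers_io

__all__ = [
    "DrugSpec",
    "PTSpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCorpus",
    "simulate_corpus",
    "regression_fixture",
    "DEFAULT_DRUGS",
    "DEFAULT_PTS",
]


@dataclasses.dataclass(frozen=True)
class DrugSpec:
    """One drug of the simulated market: marginal probability that a report
    mentions it, and whether it is the analysis target."""

    name: str
    marginal: float
    target: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.marginal <= 1:
            raise ValueError(f"marginal for {self.name!r} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class PTSpec:
    """One MedDRA Preferred Term with its background mention rate and SOC."""

    name: str
    base_rate: float
    soc: str

    def __post_init__(self) -> None:
        if not 0 <= self.base_rate <= 1:
            raise ValueError(f"base_rate for {self.name!r} outside [0, 1]")


_SOC_GI = "Gastrointestinal disorders"
_SOC_GEN = "General disorders and administration site conditions"
_SOC_NERV = "Nervous system disorders"
_SOC_PSY = "Psychiatric disorders"
_SOC_RESP = "Respiratory, thoracic and mediastinal disorders"
_SOC_MSK = "Musculoskeletal and connective tissue disorders"
_SOC_VASC = "Vascular disorders"
_SOC_MET = "Metabolism and nutrition disorders"
_SOC_BLOOD = "Blood and lymphatic system disorders"
_SOC_INV = "Investigations"
_SOC_INF = "Infections and infestations"
_SOC_SKIN = "Skin and subcutaneous tissue disorders"

DEFAULT_PTS: tuple[PTSpec, ...] = (
    PTSpec("Nausea", 0.26, _SOC_GI),
    PTSpec("Fatigue", 0.22, _SOC_GEN),
    PTSpec("Headache", 0.20, _SOC_NERV),
    PTSpec("Diarrhoea", 0.18, _SOC_GI),
    PTSpec("Dizziness", 0.16, _SOC_NERV),
    PTSpec("Vomiting", 0.16, _SOC_GI),
    PTSpec("Abdominal pain", 0.14, _SOC_GI),
    PTSpec("Insomnia", 0.14, _SOC_PSY),
    PTSpec("Dyspnoea", 0.14, _SOC_RESP),
    PTSpec("Arthralgia", 0.12, _SOC_MSK),
    PTSpec("Anxiety", 0.12, _SOC_PSY),
    PTSpec("Cough", 0.12, _SOC_RESP),
    PTSpec("Back pain", 0.11, _SOC_MSK),
    PTSpec("Hypertension", 0.10, _SOC_VASC),
    PTSpec("Decreased appetite", 0.10, _SOC_MET),
    PTSpec("Asthenia", 0.10, _SOC_GEN),
    PTSpec("Malaise", 0.09, _SOC_GEN),
    PTSpec("Anaemia", 0.08, _SOC_BLOOD),
    PTSpec("Weight decreased", 0.08, _SOC_INV),
    PTSpec("Urinary tract infection", 0.07, _SOC_INF),
    PTSpec("Hot flush", 0.06, _SOC_VASC),
    PTSpec("Dysgeusia", 0.05, _SOC_NERV),
    PTSpec("Dehydration", 0.05, _SOC_MET),
    PTSpec("Blood pressure increased", 0.04, _SOC_INV),
    PTSpec("Haemoglobin decreased", 0.035, _SOC_INV),
    PTSpec("Thrombocytopenia", 0.03, _SOC_BLOOD),
    PTSpec("White blood cell count decreased", 0.025, _SOC_INV),
    PTSpec("Neuropathy peripheral", 0.02, _SOC_NERV),
    PTSpec("Platelet count decreased", 0.0175, _SOC_INV),
    PTSpec("Photosensitivity reaction", 0.0125, _SOC_SKIN),
)

#: Filler PT assigned when every Bernoulli draw of a report comes up empty.
FILLER_PT = PTSpec("Drug ineffective", 0.0, _SOC_GEN)

DEFAULT_DRUGS: tuple[DrugSpec, ...] = (
    DrugSpec("NIRAPARIB", 0.05, target=True),
    DrugSpec("CARBOPLATIN", 0.18, False),
    DrugSpec("PACLITAXEL", 0.16, False),
    DrugSpec("BEVACIZUMAB", 0.14, False),
    DrugSpec("METFORMIN", 0.20, False),
    DrugSpec("LISINOPRIL", 0.18, False),
    DrugSpec("ATORVASTATIN", 0.16, False),
    DrugSpec("OMEPRAZOLE", 0.14, False),
    DrugSpec("LEVOTHYROXINE", 0.12, False),
)

#: Name variants used in the DRUG file for the target drug (generic, trade,
#: salt form) so name matching is exercised; prod_ai always carries the
#: generic name.
_TARGET_NAME_VARIANTS = ("NIRAPARIB", "ZEJULA", "NIRAPARIB TOSYLATE MONOHYDRATE")
_TARGET_NAME_PROBS = (0.5, 0.4, 0.1)


def _default_sex_mix() -> dict[str, float]:
    return {"F": 0.7855, "M": 0.0179, "": 0.1966}


def _default_age_band_mix() -> dict[str, float]:
    # <40 / 40-50 / >50 / unknown, as observed in the niraparib cohort
    return {"<40": 0.0050, "40-50": 0.0216, ">50": 0.3354, "": 0.6380}


def _default_occupation_mix() -> dict[str, float]:
    return {
        "CN": 0.7743,
        "MD": 0.1396,
        "OT": 0.0380,
        "HP": 0.0157,
        "PH": 0.0104,
        "LW": 0.0002,
        "": 0.0218,
    }


def _default_country_mix() -> dict[str, float]:
    return {
        "US": 0.8729,
        "JP": 0.0241,
        "CA": 0.0183,
        "FR": 0.0157,
        "GB": 0.0143,
        "DE": 0.0547,
    }


def _default_outcome_probs() -> dict[str, float]:
    return {"DE": 0.0659, "DS": 0.0026, "HO": 0.2234, "LT": 0.0506, "OT": 0.4667}


def _default_indication_mix() -> dict[str, float]:
    return {
        "Ovarian cancer": 0.7061,
        "Fallopian tube cancer": 0.0486,
        "Malignant peritoneal neoplasm": 0.0454,
        "Uterine cancer": 0.0128,
        "Product used for unknown indication": 0.1871,
    }


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the niraparib study
    conditions (demographic/reporter mixes, 2017-2021 receipt window, 18-day
    median onset, ~37% onset-date availability)."""

    n_reports: int = 10_000
    drugs: tuple[DrugSpec, ...] = DEFAULT_DRUGS
    pts: tuple[PTSpec, ...] = DEFAULT_PTS
    rr: Mapping[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    filler_pt: PTSpec = FILLER_PT
    sex_mix: dict[str, float] = dataclasses.field(default_factory=_default_sex_mix)
    age_band_mix: dict[str, float] = dataclasses.field(
        default_factory=_default_age_band_mix
    )
    occupation_mix: dict[str, float] = dataclasses.field(
        default_factory=_default_occupation_mix
    )
    country_mix: dict[str, float] = dataclasses.field(
        default_factory=_default_country_mix
    )
    outcome_probs: dict[str, float] = dataclasses.field(
        default_factory=_default_outcome_probs
    )
    indication_mix: dict[str, float] = dataclasses.field(
        default_factory=_default_indication_mix
    )
    duplicate_rate: float = 0.05
    reac_repeat_rate: float = 0.02  # same PT listed twice in one report
    onset_median_days: float = 18.0
    onset_available_rate: float = 0.3695
    date_error_rate: float = 0.01  # event date before therapy start
    start_year: int = 2017
    end_year: int = 2021
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.pts:
            raise ValueError("infeasible config: PT vocabulary is empty")
        if not any(d.target for d in self.drugs):
            raise ValueError("exactly one drug must be the target")
        for mix_name in ("sex_mix", "age_band_mix", "occupation_mix",
                         "country_mix", "indication_mix"):
            mix = getattr(self, mix_name)
            total = sum(mix.values())
            if not 0.999 <= total <= 1.001:
                raise ValueError(f"{mix_name} probabilities sum to {total:.4f}")
        for (_, _), v in self.rr.items():
            if v < 0:
                raise ValueError("relative risks must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Exact generator bookkeeping, queryable after generation."""

    rr: dict[tuple[str, str], float]
    pt_report_counts: pd.DataFrame  # pt, target_reports, background_reports
    duplicate_caseids: frozenset[str]
    n_cases: int
    n_target_cases: int
    onset_median_days: float
    capped_probabilities: int  # how many base*rr products were clipped at 1

    def to_csv(self, path) -> None:
        self.pt_report_counts.to_csv(path, index=False)


_FILES = {
    "DEMO": "DEMO.txt",
    "DRUG": "DRUG.txt",
    "REAC": "REAC.txt",
    "OUTC": "OUTC.txt",
    "INDI": "INDI.txt",
    "THER": "THER.txt",
}


@dataclasses.dataclass
class SyntheticCorpus:
    """Generated tables (as DataFrames of strings) plus the ground truth."""

    frames: dict[str, pd.DataFrame]
    ground_truth: GroundTruth
    config: SimulationConfig

    def write(self, directory) -> dict[str, Path]:
        """Emit the ``$``-delimited files plus ground_truth.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for kind, fname in _FILES.items():
            path = directory / fname
            self.frames[kind].to_csv(path, sep="$", index=False,
                                     lineterminator="\n")
            paths[kind] = path
        self.ground_truth.to_csv(directory / "ground_truth.csv")
        return paths

    def to_records(self) -> dict[str, list]:
        """The same content as typed records, bypassing serialization."""
        out: dict[str, list] = {}
        for kind in _FILES:
            buf = io.StringIO()
            self.frames[kind].to_csv(buf, sep="$", index=False,
                                     lineterminator="\n")
            buf.seek(0)
            result = faers_io.parse_table(buf, kind)
            if result.n_errors:
                raise AssertionError(
                    f"generator emitted malformed {kind} rows: {result.log()}"
                )
            out[kind] = result.records
        return out


def _sample_mix(rng: np.random.Generator, mix: dict[str, float], n: int) -> np.ndarray:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return np.array(keys, dtype=object)[idx]


def _render_dates(ordinals: np.ndarray) -> np.ndarray:
    out = np.empty(len(ordinals), dtype=object)
    for i, o in enumerate(ordinals):
        d = datetime.date.fromordinal(int(o))
        out[i] = f"{d.year:04d}{d.month:02d}{d.day:02d}"
    return out


def simulate_corpus(config: SimulationConfig) -> SyntheticCorpus:
    """Generate one corpus; a single seeded RNG stream drives every draw, so
    the same config always reproduces byte-identical files."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.drugs
    pts = config.pts
    k, m = len(drugs), len(pts)
    target_idx = next(i for i, d in enumerate(drugs) if d.target)

    # --- drug sets -------------------------------------------------------
    marginals = np.array([d.marginal for d in drugs])
    drug_mat = rng.random((n, k)) < marginals
    empty = ~drug_mat.any(axis=1)
    if empty.any():
        probs = marginals / marginals.sum()
        fill = rng.choice(k, size=int(empty.sum()), p=probs)
        drug_mat[np.nonzero(empty)[0], fill] = True
    target_present = drug_mat[:, target_idx]

    # --- PT mentions -----------------------------------------------------
    base = np.array([p.base_rate for p in pts])
    eff = np.tile(base, (n, 1))
    capped = 0
    for (drug_name, pt_name), rr in config.rr.items():
        if rr == 1.0:
            continue
        ki = next(i for i, d in enumerate(drugs) if d.name == drug_name)
        mi = next(i for i, p in enumerate(pts) if p.name == pt_name)
        rows = drug_mat[:, ki]
        boosted = base[mi] * rr
        if boosted > 1.0:
            capped += 1
            boosted = 1.0
        eff[rows, mi] = np.maximum(eff[rows, mi], boosted)
    pt_mat = rng.random((n, m)) < eff
    filler = ~pt_mat.any(axis=1)

    # exact ground-truth bookkeeping at report level
    a_true = (pt_mat & target_present[:, None]).sum(axis=0)
    c_true = (pt_mat & ~target_present[:, None]).sum(axis=0)
    gt_counts = pd.DataFrame(
        {
            "pt": [p.name for p in pts] + [config.filler_pt.name],
            "target_reports": list(a_true)
            + [int((filler & target_present).sum())],
            "background_reports": list(c_true)
            + [int((filler & ~target_present).sum())],
        }
    )

    # --- demographics ----------------------------------------------------
    sex = _sample_mix(rng, config.sex_mix, n)
    band = _sample_mix(rng, config.age_band_mix, n)
    age = np.full(n, "", dtype=object)
    lo_hi = {"<40": (20, 39), "40-50": (40, 50), ">50": (51, 85)}
    for b, (lo, hi) in lo_hi.items():
        mask = band == b
        if mask.any():
            vals = rng.integers(lo, hi + 1, size=int(mask.sum()))
            age[mask] = [str(v) for v in vals]
    age_cod = np.where(age == "", "", "YR")
    occp = _sample_mix(rng, config.occupation_mix, n)
    country = _sample_mix(rng, config.country_mix, n)

    # --- dates -----------------------------------------------------------
    d0 = datetime.date(config.start_year, 1, 1).toordinal()
    d1 = datetime.date(config.end_year, 12, 31).toordinal()
    fda_ord = rng.integers(d0, d1 + 1, size=n)
    onset_days = np.floor(
        rng.exponential(config.onset_median_days / np.log(2.0), size=n)
    ).astype(int)
    report_lag = rng.integers(0, 61, size=n)
    start_ord = fda_ord - report_lag - onset_days
    event_ord = start_ord + onset_days
    onset_avail = rng.random(n) < config.onset_available_rate
    date_error = (rng.random(n) < config.date_error_rate) & onset_avail
    event_ord = np.where(date_error,
                         start_ord - rng.integers(1, 11, size=n), event_ord)
    # unavailable onset: event date absent; some therapy starts only partial
    start_partial = rng.random(n) < 0.3

    # --- duplicates ------------------------------------------------------
    dup = rng.random(n) < config.duplicate_rate
    stale_offset = rng.integers(30, 366, size=n)

    caseids = np.array([str(1_000_001 + i) for i in range(n)], dtype=object)
    version = np.where(dup, 2, 1)
    primaryids = np.array(
        [f"{cid}{v}" for cid, v in zip(caseids, version)], dtype=object
    )
    stale_pids = np.array([f"{cid}1" for cid in caseids], dtype=object)

    fda_str = _render_dates(fda_ord)
    event_str = np.where(onset_avail, _render_dates(event_ord), "")
    start_full = _render_dates(start_ord)
    start_str = np.where(
        onset_avail,
        start_full,
        np.where(start_partial,
                 np.array([s[:6] for s in start_full], dtype=object), start_full),
    )

    demo_rows = {
        "primaryid": list(primaryids),
        "caseid": list(caseids),
        "fda_dt": list(fda_str),
        "event_dt": list(event_str),
        "age": list(age),
        "age_cod": list(age_cod),
        "sex": list(sex),
        "occp_cod": list(occp),
        "occr_country": list(country),
    }
    # stale versions: same demographics, earlier receipt date
    dup_idx = np.nonzero(dup)[0]
    stale_fda = _render_dates(fda_ord[dup_idx] - stale_offset[dup_idx])
    for j, i in enumerate(dup_idx):
        demo_rows["primaryid"].append(stale_pids[i])
        demo_rows["caseid"].append(caseids[i])
        demo_rows["fda_dt"].append(stale_fda[j])
        demo_rows["event_dt"].append(event_str[i])
        demo_rows["age"].append(age[i])
        demo_rows["age_cod"].append(age_cod[i])
        demo_rows["sex"].append(sex[i])
        demo_rows["occp_cod"].append(occp[i])
        demo_rows["occr_country"].append(country[i])
    demo_df = pd.DataFrame(demo_rows)

    # --- DRUG / INDI / THER ---------------------------------------------
    target_variant = rng.choice(
        len(_TARGET_NAME_VARIANTS), size=n, p=_TARGET_NAME_PROBS
    )
    other_roles = np.array(["SS", "C", "I"], dtype=object)
    drug_cols: dict[str, list] = {c: [] for c in
                                  ("primaryid", "drug_seq", "role_cod",
                                   "drugname", "prod_ai")}
    indi_cols: dict[str, list] = {c: [] for c in
                                  ("primaryid", "indi_drug_seq", "indi_pt")}
    ther_cols: dict[str, list] = {c: [] for c in
                                  ("primaryid", "dsg_drug_seq", "start_dt")}
    indication = _sample_mix(rng, config.indication_mix, n)
    role_draws = rng.choice(3, size=(n, k), p=[0.3, 0.5, 0.2])

    def emit_drug_rows(pid: str, i: int) -> None:
        present = np.nonzero(drug_mat[i])[0]
        ps_ki = target_idx if target_present[i] else present[0]
        for seq, ki in enumerate(present, start=1):
            if ki == target_idx:
                name = _TARGET_NAME_VARIANTS[target_variant[i]]
                ai = "NIRAPARIB" if drugs[ki].name == "NIRAPARIB" else drugs[ki].name
            else:
                name = drugs[ki].name
                ai = drugs[ki].name
            role = "PS" if ki == ps_ki else other_roles[role_draws[i, ki]]
            drug_cols["primaryid"].append(pid)
            drug_cols["drug_seq"].append(str(seq))
            drug_cols["role_cod"].append(role)
            drug_cols["drugname"].append(name)
            drug_cols["prod_ai"].append(ai)
            if role == "PS":
                if ki == target_idx:
                    indi_pt = indication[i]
                else:
                    indi_pt = "Product used for unknown indication"
                indi_cols["primaryid"].append(pid)
                indi_cols["indi_drug_seq"].append(str(seq))
                indi_cols["indi_pt"].append(indi_pt)
                ther_cols["primaryid"].append(pid)
                ther_cols["dsg_drug_seq"].append(str(seq))
                ther_cols["start_dt"].append(start_str[i])

    for i in range(n):
        emit_drug_rows(primaryids[i], i)
    for i in dup_idx:
        emit_drug_rows(stale_pids[i], i)

    # --- REAC / OUTC -----------------------------------------------------
    repeat = rng.random(n) < config.reac_repeat_rate
    reac_cols: dict[str, list] = {"primaryid": [], "pt": []}

    def emit_reac_rows(pid: str, i: int) -> None:
        terms = [pts[mi].name for mi in np.nonzero(pt_mat[i])[0]]
        if not terms:
            terms = [config.filler_pt.name]
        for t in terms:
            reac_cols["primaryid"].append(pid)
            reac_cols["pt"].append(t)
        if repeat[i]:
            reac_cols["primaryid"].append(pid)
            reac_cols["pt"].append(terms[0])

    for i in range(n):
        emit_reac_rows(primaryids[i], i)
    for i in dup_idx:
        emit_reac_rows(stale_pids[i], i)

    outc_draw = {
        code: rng.random(n) < p for code, p in config.outcome_probs.items()
    }
    outc_cols: dict[str, list] = {"primaryid": [], "outc_cod": []}
    for code, mask in outc_draw.items():
        for i in np.nonzero(mask)[0]:
            outc_cols["primaryid"].append(primaryids[i])
            outc_cols["outc_cod"].append(code)

    frames = {
        "DEMO": demo_df,
        "DRUG": pd.DataFrame(drug_cols),
        "REAC": pd.DataFrame(reac_cols),
        "OUTC": pd.DataFrame(outc_cols).sort_values(
            ["primaryid", "outc_cod"], kind="stable"
        ).reset_index(drop=True),
        "INDI": pd.DataFrame(indi_cols),
        "THER": pd.DataFrame(ther_cols),
    }
    gt = GroundTruth(
        rr=dict(config.rr),
        pt_report_counts=gt_counts,
        duplicate_caseids=frozenset(caseids[dup_idx]),
        n_cases=n,
        n_target_cases=int(target_present.sum()),
        onset_median_days=config.onset_median_days,
        capped_probabilities=capped,
    )
    return SyntheticCorpus(frames=frames, ground_truth=gt, config=config)


#: Seed of the deterministic regression fixture.
REGRESSION_SEED = 20221129


def regression_fixture() -> SyntheticCorpus:
    """A fixed ~200-report corpus with planted associations, used for
    golden-file tests.  Regenerating with the fixed seed is byte-identical."""
    config = SimulationConfig(
        n_reports=200,
        drugs=(
            DrugSpec("NIRAPARIB", 0.30, target=True),
            *[d for d in DEFAULT_DRUGS if not d.target],
        ),
        rr={
            ("NIRAPARIB", "Thrombocytopenia"): 8.0,
            ("NIRAPARIB", "Nausea"): 3.0,
            ("NIRAPARIB", "Photosensitivity reaction"): 12.0,
        },
        duplicate_rate=0.10,
        seed=REGRESSION_SEED,
    )
    return simulate_corpus(config)
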