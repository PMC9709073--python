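"""End-to-end orchestration: ingest -> cohort -> tables -> signals -> onset.

The pipeline reads a directory of FAERS-style tables, deduplicates case
versions, builds the target-drug primary-suspect cohort, computes all four
disproportionality statistics at PT and SOC level, applies the signal
criteria, and summarizes time-to-onset.  Report CSVs round statistics to two
decimals; a ``_full`` companion keeps full precision for machine use.  A run
log records the report count after every filtering step.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import contingency, faers_io, onset as onset_mod, signal_stats

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_label_terms",
           "bundled_soc_map_path", "bundled_label_terms_path"]

_TABLE_FILES = {
    "DEMO": "DEMO.txt",
    "DRUG": "DRUG.txt",
    "REAC": "REAC.txt",
    "OUTC": "OUTC.txt",
    "INDI": "INDI.txt",
    "THER": "THER.txt",
}


def bundled_soc_map_path() -> Path:
    """Path of the small demo PT->SOC mapping shipped with the package
    (MedDRA itself is licensed and must be supplied by the user)."""
    return Path(importlib.resources.files("pvsignal") / "data" / "demo_soc_map.csv")


def bundled_label_terms_path() -> Path:
    return Path(
        importlib.resources.files("pvsignal") / "data" / "demo_label_terms.txt"
    )


def load_label_terms(path) -> list[str]:
    """Plain-text label list, one term per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


@dataclasses.dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    target_names: Sequence[str] = ("niraparib", "zejula")
    soc_map_path: str | None = None  # None -> bundled demo mapping
    label_terms_path: str | None = None
    thresholds: signal_stats.Thresholds = dataclasses.field(
        default_factory=signal_stats.Thresholds
    )
    exclude_consumers: bool = False
    ebgm_mode: str = "simplified"  # or "shrinkage"
    ic_variant: str = "delta"  # or "gamma"
    ebgm_z: float = 1.645
    level: str = "both"  # pt | soc | both
    haldane: bool = False
    seed: int = 0  # only meaningful for synthetic upstream steps

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = signal_stats.Thresholds.from_dict(th)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_names"] = list(self.target_names)
        return d


@dataclasses.dataclass
class PipelineResult:
    output_dir: Path
    counts: dict[str, int]
    characteristics: pd.DataFrame
    pt_signals: pd.DataFrame
    soc_signals: pd.DataFrame
    onset_summary: onset_mod.OnsetSummary
    warnings: list[str]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage, earlier artifacts are
    kept on disk."""


def _parse_inputs(input_dir: Path) -> dict[str, faers_io.ParseResult]:
    results = {}
    for kind, fname in _TABLE_FILES.items():
        path = input_dir / fname
        if not path.exists():
            if kind in ("DEMO", "DRUG", "REAC"):
                raise PipelineStageError(f"ingest: required file missing: {path}")
            results[kind] = faers_io.ParseResult(kind, [], 0, [])
            continue
        with open(path, encoding="utf-8", errors="replace") as fh:
            results[kind] = faers_io.parse_table(fh, kind)
    return results


def _signal_frame(
    tables: contingency.TableSet,
    cfg: RunConfig,
    label_terms: Sequence[str],
    soc_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    rows = []
    model = None
    if cfg.ebgm_mode == "shrinkage":
        model = signal_stats.GammaPoissonModel.fit(tables.tables)
    for t in tables:
        est = signal_stats.compute_estimates(
            t,
            haldane=cfg.haldane,
            ic_variant=cfg.ic_variant,
            ebgm_mode=cfg.ebgm_mode,
            ebgm_model=model,
            ebgm_z=cfg.ebgm_z,
        )
        flags = signal_stats.apply_criteria(
            est, t.a, cfg.thresholds, label_terms, term=t.term
        )
        rows.append(
            {
                "level": t.level,
                "soc": (soc_of or {}).get(t.term, t.term if t.level == "soc" else ""),
                "term": t.term,
                "a": int(t.a),
                "ror": est.ror,
                "ror_low": est.ror_low,
                "ror_high": est.ror_high,
                "prr": est.prr,
                "chi2": est.chi2,
                "ic": est.ic,
                "ic025": est.ic025,
                "ebgm": est.ebgm,
                "ebgm05": est.ebgm05,
                "ror_sig": flags.ror_sig,
                "prr_sig": flags.prr_sig,
                "ic_sig": flags.ic_sig,
                "ebgm_sig": flags.ebgm_sig,
                "all_four": flags.all_four,
                "expected": flags.expected,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["a", "term"], ascending=[False, True]).reset_index(
            drop=True
        )
    return df


_STAT_COLS = ["ror", "ror_low", "ror_high", "prr", "chi2", "ic", "ic025",
              "ebgm", "ebgm05"]


def _write_report(df: pd.DataFrame, path: Path) -> None:
    """Two-decimal report CSV plus a full-precision companion."""
    full_path = path.with_name(path.stem + "_full.csv")
    df.to_csv(full_path, index=False)
    rounded = df.copy()
    for col in _STAT_COLS:
        if col in rounded.columns:
            rounded[col] = rounded[col].map(
                lambda v: "" if isinstance(v, float) and math.isnan(v)
                else f"{v:.2f}"
            )
    rounded.to_csv(path, index=False)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``cfg.output_dir``.

    Emits characteristics.csv, soc_signals.csv, pt_signals.csv,
    pt_signals_all_four.csv, onset_summary.csv, onset_bins.csv, run_log.txt
    and a config echo (run_config.yaml).  An empty target match produces
    empty signal tables with a warning, not a failure.
    """
    input_dir = Path(cfg.input_dir)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    counts: dict[str, int] = {}
    log_lines: list[str] = []

    with open(out / "run_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)

    # ingest ---------------------------------------------------------------
    parsed = _parse_inputs(input_dir)
    for kind, res in parsed.items():
        log_lines.append(res.log())
    demo_all = parsed["DEMO"].records
    counts["reports_read"] = len(demo_all)

    # dedup ----------------------------------------------------------------
    demo = faers_io.deduplicate(demo_all)
    counts["deduplicated_cases"] = len(demo)

    # cohort ---------------------------------------------------------------
    try:
        coh = cohort_mod.build_cohort(demo, parsed["DRUG"].records,
                                      cfg.target_names)
    except ValueError as err:
        raise PipelineStageError(f"cohort: {err}") from err
    if cfg.exclude_consumers:
        coh = cohort_mod.exclude_consumers(coh, demo)
        demo = [r for r in demo if r.caseid in coh.all_cases]
        counts["after_consumer_exclusion"] = len(demo)
    counts["target_cohort"] = coh.n_target
    if coh.n_target == 0:
        warnings.append("target drug matched no reports; signal tables empty")

    chars = cohort_mod.summarize_characteristics(
        coh, demo, parsed["OUTC"].records, parsed["INDI"].records
    )
    chars.to_csv(out / "characteristics.csv", index=False)

    # contingency + signals ------------------------------------------------
    case_of = {r.primaryid: r.caseid for r in demo}
    events = [e for e in parsed["REAC"].records if e.primaryid in case_of]
    counts["events"] = len(events)
    label_terms = load_label_terms(
        cfg.label_terms_path or bundled_label_terms_path()
    )
    soc_map = contingency.SocMap.from_csv(
        cfg.soc_map_path or bundled_soc_map_path()
    )

    pt_df = pd.DataFrame()
    soc_df = pd.DataFrame()
    try:
        if cfg.level in ("pt", "both"):
            pt_tables = contingency.build_tables(
                coh, events, "pt", soc_map, case_of=case_of
            )
            counts["pt_tables"] = len(pt_tables)
            soc_of = {
                t.term: soc_map.get(t.term) or contingency.UNMAPPED_SOC
                for t in pt_tables
            }
            pt_df = _signal_frame(pt_tables, cfg, label_terms, soc_of)
            _write_report(pt_df, out / "pt_signals.csv")
            all_four = pt_df[pt_df["all_four"]] if not pt_df.empty else pt_df
            _write_report(all_four, out / "pt_signals_all_four.csv")
            counts["pt_signals_all_four"] = int(len(all_four))
        if cfg.level in ("soc", "both"):
            soc_tables = contingency.build_tables(
                coh, events, "soc", soc_map, case_of=case_of
            )
            counts["soc_tables"] = len(soc_tables)
            if soc_tables.unmapped_pts:
                warnings.append(
                    "PTs without SOC mapping routed to 'Unmapped': "
                    + ", ".join(sorted(soc_tables.unmapped_pts))
                )
            soc_df = _signal_frame(soc_tables, cfg, label_terms)
            _write_report(soc_df, out / "soc_signals.csv")
    except Exception as err:  # noqa: BLE001 - stage name must surface
        raise PipelineStageError(f"signals: {err}") from err

    # onset ----------------------------------------------------------------
    try:
        onset_res = onset_mod.compute_onset(demo, parsed["THER"].records, coh)
        summary = onset_mod.summarize_onset(onset_res.records)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(f"onset: {err}") from err
    counts["onset_records"] = summary.n_with_onset
    pd.DataFrame(
        {
            "statistic": ["n_with_onset", "median_days", "q1_days", "q3_days"],
            "value": [summary.n_with_onset, summary.median_days,
                      summary.q1, summary.q3],
        }
    ).to_csv(out / "onset_summary.csv", index=False)
    summary.bins.to_csv(out / "onset_bins.csv", index=False)

    # run log --------------------------------------------------------------
    log_lines.append("filter funnel:")
    log_lines += [f"  {k}: {v}" for k, v in counts.items()]
    log_lines += [f"warning: {w}" for w in warnings]
    for reason, cnt in sorted(onset_res.exclusions.items()):
        log_lines.append(f"onset excluded ({reason}): {cnt}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n",
                                     encoding="utf-8")

    return PipelineResult(
        output_dir=out,
        counts=counts,
        characteristics=chars,
        pt_signals=pt_df,
        soc_signals=soc_df,
        onset_summary=summary,
        warnings=warnings,
    )
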