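"""End-to-end pipeline orchestration.

Runs the stages in order — load -> exclusion cascade -> record
derivation -> characteristics table -> ROR signals -> time-to-onset ->
logistic risk model — and writes one CSV artifact per stage plus a
machine-readable run manifest (config echo, input/output digests,
package version).  Input is either the four CSV tables or a synthetic
generator config; exactly one of the two must be supplied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import apply_exclusions, derive_records, tabulate_characteristics
from .logistic import design_matrix, model_report
from .onset import collect_onsets, histogram_frame, summaries_by_drug
from .reports import read_tables
from .signals import detect_signals, signals_frame
from .synthetic import GeneratorConfig, generate_files
from .terminology import load_drug_dictionary, load_event_dictionary

logger = logging.getLogger("jaderpv")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    demo: Path | None = None
    drug: Path | None = None
    reac: Path | None = None
    hist: Path | None = None
    generator: GeneratorConfig | None = None
    drug_dict_path: Path | None = None
    event_dict_path: Path | None = None
    confidence: float = 0.95
    cap_days: int = 730
    out_dir: Path = Path("jaderpv_out")

    def validate(self) -> None:
        paths = [self.demo, self.drug, self.reac, self.hist]
        have_paths = all(p is not None for p in paths)
        any_paths = any(p is not None for p in paths)
        if self.generator is not None and any_paths:
            raise ValueError("supply either input tables or a generator config, not both")
        if self.generator is None and not have_paths:
            raise ValueError("all four input tables (or a generator config) are required")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        logger.info("generating synthetic tables (n=%d, seed=%d)",
                    config.generator.n_cases, config.generator.seed)
        gen_dir = out / "generated"
        generate_files(config.generator, gen_dir)
        demo, drug = gen_dir / "demo.csv", gen_dir / "drug.csv"
        reac, hist = gen_dir / "reac.csv", gen_dir / "hist.csv"
    else:
        demo, drug = Path(config.demo), Path(config.drug)
        reac, hist = Path(config.reac), Path(config.hist)

    drug_dict = load_drug_dictionary(config.drug_dict_path)
    event_dict = load_event_dictionary(config.event_dict_path)

    cases, load_summary = read_tables(demo, drug, reac, hist)
    logger.info("loaded %d cases (%d orphan rows, %d row errors)",
                load_summary.n_cases, len(load_summary.orphans),
                len(load_summary.row_errors))

    filtered, report = apply_exclusions(cases, drug_dict)
    for rule, n in report.removed:
        logger.info("exclusion %-24s removed %6d cases", rule, n)
    logger.info("analysis set: %d of %d cases", report.final_count,
                report.initial_count)
    report.to_frame().to_csv(out / "exclusions.csv", index=False)

    records = derive_records(filtered, drug_dict, event_dict)
    exposed = [r for r in records if r.exposed_vd3]
    logger.info("exposed cases: %d (%d with the target event)",
                len(exposed), sum(r.aki for r in exposed))

    tabulate_characteristics(exposed).to_csv(
        out / "characteristics.csv", index=False)

    sig = detect_signals(records, confidence=config.confidence)
    signals_frame(sig).to_csv(out / "signals.csv", index=False)

    observations, excluded = collect_onsets(
        filtered, drug_dict, event_dict, cap_days=config.cap_days)
    if observations:
        summaries = summaries_by_drug(observations)
        pd.DataFrame([
            {"drug": name, "n": s.n, "median_weeks": s.median_weeks,
             "q1_weeks": s.q1_weeks, "q3_weeks": s.q3_weeks}
            for name, s in summaries.items()
        ]).to_csv(out / "onset_summary.csv", index=False)
        histogram_frame(summaries["all"]).to_csv(
            out / "onset_histogram.csv", index=False)
    else:
        logger.warning("no computable onset observations")

    X = design_matrix(exposed)
    table, diagnostics = model_report(X, confidence=config.confidence)
    table.to_csv(out / "model_report.csv", index=False)

    manifest = {
        "package": "jaderpv",
        "version": __version__,
        "python": platform.python_version(),
        "config": {
            "confidence": config.confidence,
            "cap_days": config.cap_days,
            "generator": (dataclasses.asdict(config.generator)
                          if config.generator is not None else None),
        },
        "inputs": {p.name: _sha256(p) for p in (demo, drug, reac, hist)},
        "load": {"n_cases": load_summary.n_cases,
                 "orphans": len(load_summary.orphans),
                 "row_errors": len(load_summary.row_errors)},
        "onset_exclusions": excluded,
        "diagnostics": diagnostics,
        "outputs": {},
    }
    for name in ("exclusions.csv", "characteristics.csv", "signals.csv",
                 "onset_summary.csv", "onset_histogram.csv",
                 "model_report.csv"):
        p = out / name
        if p.exists():
            manifest["outputs"][name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
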