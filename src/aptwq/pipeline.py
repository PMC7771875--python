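"""End-to-end orchestration: cohort -> statistics -> artifact bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .cohort import CohortSimParams, CohortTable, load_table1_fixture, simulate_cohort_table
from .config import RunConfig
from .errors import ConfigError
from .grading import ThresholdRule, apply_exclusions
from .reports import cohort_statistics, render_tables, summary_dict

log = logging.getLogger("aptwq")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    return str(obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def resolve_cohort(config: RunConfig) -> CohortTable:
    """Load or simulate the cohort named by the configuration."""
    if config.cohort_source == "fixture":
        return load_table1_fixture()
    if config.cohort_source == "simulate":
        return simulate_cohort_table(CohortSimParams(seed=config.seed))
    path = Path(config.cohort_path)
    if not path.exists():
        raise ConfigError(f"[cohort] cohort file not found: {path}")
    return CohortTable.from_csv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run the subject-level pipeline and write the artifact bundle.

    Writes the final cohort CSV, per-rule classification audits, a
    full-precision JSON summary, rendered tables, and a manifest with
    content hashes of every output.  Deterministic under the seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("[cohort] source=%s", config.cohort_source)
    cohort = resolve_cohort(config)
    final = apply_exclusions(cohort)
    log.info(
        "[cohort] %d subjects loaded, %d excluded, groups %s",
        len(cohort),
        len(cohort) - len(final),
        final.group_sizes(),
    )
    for entry in final.exclusion_log:
        log.info("[cohort] excluded subject %s: %s", entry["subject_id"], entry["reason"])

    rules = tuple(ThresholdRule.parse(r) for r in config.rules)
    log.info("[stats] rules=%s prob_cutoff=%.2f", config.rules, config.prob_cutoff)
    results = cohort_statistics(final, rules=rules, prob_cutoff=config.prob_cutoff)

    written = {}

    def _write_text(name: str, text: str):
        path = out_dir / name
        path.write_text(text)
        written[name] = _sha256(path)

    final.to_csv(out_dir / "cohort_final.csv")
    written["cohort_final.csv"] = _sha256(out_dir / "cohort_final.csv")
    for name, audit in results["threshold_audits"].items():
        fname = f"audit_{name.replace('>', '_gt_')}.csv"
        audit.per_subject.to_csv(out_dir / fname, index=False)
        written[fname] = _sha256(out_dir / fname)
    _write_text(
        "summary.json",
        json.dumps(_jsonify(summary_dict(results)), indent=2, sort_keys=True) + "\n",
    )
    _write_text("tables.txt", render_tables(results))

    manifest = {
        "seed": config.seed,
        "cohort_source": config.cohort_source,
        "n_final": len(final),
        "files": dict(sorted(written.items())),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    log.info("[report] wrote %d artifacts to %s", len(written) + 1, out_dir)
    return {"results": results, "manifest": manifest, "output_dir": str(out_dir)}
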