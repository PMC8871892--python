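"""Study orchestration: calibrate -> base case -> scenarios -> comparison tables.

``run_full_study`` reproduces the whole experimental design: the calibrated
base case plus scenarios 1–7, each as a set of seeded replications, writing
per-scenario summaries, the percent-change table of median overall turnaround
times, the hourly crowd-change table, and a run manifest from which the run
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .metrics import CROWD_HOURS, percent_change, pooled_tt
from .scenarios import SCENARIO_IDS, make_scenario, run_experiment

__all__ = ["RunManifest", "run_scenario_to_dir", "compare_summaries", "run_full_study"]

log = logging.getLogger("ogclinic")


@dataclass
class RunManifest:
    config_digest: str
    master_seed: int
    scenario_ids: list
    n_replications: int
    days: int
    version: str
    started_utc: str
    finished_utc: str


def _config_digest(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_scenario_to_dir(config: dict, scenario_id: str, out_dir: Path, seed: int,
                        reps: int, days: int) -> dict:
    """Run one scenario and write its summary JSON and per-patient TT CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = make_scenario(scenario_id)
    t0 = time.perf_counter()
    rs = run_experiment(config, scenario, n_replications=reps, days=days, master_seed=seed)
    summary = rs.summary()
    _write_json(out_dir / "summary.json", summary)
    pooled_tt(rs).to_csv(out_dir / "patients.csv", index=False)
    crowd = pd.DataFrame(
        {f"{h:02d}:00": [summary["hourly_crowd"][f"{h:02d}:00"]] for h in CROWD_HOURS}
    )
    crowd.to_csv(out_dir / "hourly_crowd.csv", index=False)
    log.info("scenario=%s seed=%d reps=%d days=%d patients=%d runtime=%.1fs",
             scenario_id, seed, reps, days,
             summary["patients_per_replication"] * reps, time.perf_counter() - t0)
    return summary


def compare_summaries(base: dict, scenario: dict) -> dict:
    """Percent change of median overall TT per class and of hourly crowd."""
    out = {"scenario": scenario["scenario"], "overall_tt_change_pct": {},
           "crowd_change_pct": {}}
    for group, classes in (("public", ("PUBLIC_OBS", "PUBLIC_GYN")), ("private", ("PRIVATE",))):
        b = [base["turnaround_times"][k]["overall_tt"]["median"] for k in classes
             if k in base["turnaround_times"]]
        s = [scenario["turnaround_times"][k]["overall_tt"]["median"] for k in classes
             if k in scenario["turnaround_times"]]
        if b and s:
            out["overall_tt_change_pct"][group] = percent_change(
                float(pd.Series(s).mean()), float(pd.Series(b).mean())
            )
    for k in ("PUBLIC_OBS", "PUBLIC_GYN", "PRIVATE"):
        if k in base["turnaround_times"] and k in scenario["turnaround_times"]:
            out["overall_tt_change_pct"][k] = percent_change(
                scenario["turnaround_times"][k]["overall_tt"]["median"],
                base["turnaround_times"][k]["overall_tt"]["median"],
            )
    for hour, b in base["hourly_crowd"].items():
        s = scenario["hourly_crowd"][hour]
        out["crowd_change_pct"][hour] = percent_change(s, b) if b > 0 else None
    return out


def run_full_study(config: dict, out_dir, seed: int, reps: int = 30, days: int = 5,
                   scenario_ids=SCENARIO_IDS) -> dict:
    """Execute the full experiment battery; returns the comparison table."""
    if not config.get("calibration", {}).get("calibrated", False):
        raise RuntimeError("configuration lacks calibrated parameters: run `calibrate` first")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    summaries = {}
    for sid in scenario_ids:
        summaries[sid] = run_scenario_to_dir(config, sid, out_dir / f"scenario_{sid}",
                                             seed, reps, days)
    comparisons = {}
    if "base" in summaries:
        for sid, summ in summaries.items():
            if sid == "base":
                continue
            comparisons[sid] = compare_summaries(summaries["base"], summ)
        _write_json(out_dir / "tt_change.json", comparisons)
        rows = []
        for sid, comp in comparisons.items():
            row = {"scenario": sid}
            row.update({f"tt_{k}": v for k, v in comp["overall_tt_change_pct"].items()})
            row.update({f"crowd_{h}": v for h, v in comp["crowd_change_pct"].items()})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "percent_change.csv", index=False)

    manifest = RunManifest(
        config_digest=_config_digest(config),
        master_seed=seed,
        scenario_ids=list(scenario_ids),
        n_replications=reps,
        days=days,
        version=__version__,
        started_utc=started,
        finished_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    _write_json(out_dir / "manifest.json", asdict(manifest))
    return comparisons
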