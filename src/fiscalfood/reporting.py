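"""Output tables: tidy CSVs, a JSON summary and a run log per scenario."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .scenarios import ScenarioResult


def _tidy_equilibrium_path(result: ScenarioResult) -> pd.DataFrame:
    """Long (year, variable, account, value) table for both runs."""
    rows = []
    for tag, path in (("policy", result.policy), ("counterfactual", result.count)):
        if path is None:
            continue
        for year, eq in path.eqs.items():
            rows.append({"run": tag, "year": year, "variable": "gdp_real", "account": "total", "value": eq.gdp_real})
            rows.append({"run": tag, "year": year, "variable": "gdp_nominal", "account": "total", "value": eq.gdp_nominal})
            rows.append({"run": tag, "year": year, "variable": "cons_real", "account": "total", "value": eq.cons_real})
            rows.append({"run": tag, "year": year, "variable": "exchange_rate", "account": "total", "value": eq.exr})
            rows.append({"run": tag, "year": year, "variable": "tariff_revenue", "account": "total", "value": eq.tariff_revenue})
            for c, m in enumerate(eq.m):
                rows.append({"run": tag, "year": year, "variable": "imports", "account": str(c), "value": float(m)})
    return pd.DataFrame(rows, columns=["run", "year", "variable", "account", "value"])


def report(results: list[ScenarioResult], out_dir, config: dict | None = None) -> list[Path]:
    """Write scenario outputs to ``out_dir``; returns the files written.

    Emits per-scenario per-year delta tables, one combined summary CSV/JSON,
    and a run log.  An empty result list yields header-only tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary_rows = []
    for res in results:
        name = res.spec.name
        per_year = out / f"{name}_per_year.csv"
        res.per_year.to_csv(per_year, index=False)
        written.append(per_year)
        eq_path = out / f"{name}_equilibrium_path.csv"
        _tidy_equilibrium_path(res).to_csv(eq_path, index=False)
        written.append(eq_path)
        summary_rows.append({"scenario": name, **res.summary})

    summary_cols = ["scenario"] + (list(results[0].summary) if results else [])
    summary = pd.DataFrame(summary_rows, columns=summary_cols)
    summary_csv = out / "summary.csv"
    summary.to_csv(summary_csv, index=False)
    written.append(summary_csv)

    payload = {
        "scenarios": {
            res.spec.name: {"spec": asdict(res.spec), "summary": res.summary} for res in results
        },
        "config": config or {},
    }
    summary_json = out / "summary.json"
    summary_json.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    written.append(summary_json)

    log = out / "run.log"
    lines = [f"scenarios: {len(results)}"]
    for res in results:
        if res.policy is not None:
            worst = max(abs(eq.walras) for eq in res.policy.eqs.values())
            lines.append(f"{res.spec.name}: max |Walras residual| = {worst:.3e}")
    log.write_text("\n".join(lines) + "\n")
    written.append(log)
    return written


def read_summary(out_dir) -> dict:
    """Re-read a written JSON summary."""
    return json.loads((Path(out_dir) / "summary.json").read_text())
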