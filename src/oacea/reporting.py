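"""Report writers and pipeline orchestration.

Human-readable tables round currency to whole dollars; JSON keeps full
precision. ``run_full_analysis`` chains base case, tornado, break-even
thresholds and PSA into one output directory with a reproducibility
manifest (seed, package version, model hash) and removes partial output
on failure.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .model import Model
from .psa import run_psa
from .sensitivity import find_threshold, tornado
from .tree import NoThresholdError

__all__ = ["run_base_case", "run_full_analysis", "strategy_table"]


def strategy_table(model: Model) -> pd.DataFrame:
    """One row per strategy: label, expected cost, expected effect."""
    pairs = model.evaluate()
    return pd.DataFrame(
        [
            {"label": label, "expected_cost": float(pairs[label].cost),
             "expected_effect": float(pairs[label].effect)}
            for label in model.strategies
        ]
    )


def run_base_case(model: Model) -> dict:
    """Base-case report: per-strategy totals plus the incremental result
    of every declared comparison."""
    pairs = model.evaluate()
    return {
        "model": model.name,
        "strategies": {
            label: {"expected_cost": float(pairs[label].cost),
                    "expected_effect": float(pairs[label].effect)}
            for label in model.strategies
        },
        "comparisons": [
            {"new": new, "standard": std,
             **model.incremental(i).to_dict()}
            for i, (new, std) in enumerate(model.comparisons)
        ],
    }


def _model_hash(model: Model) -> str:
    blob = yaml.safe_dump(model.config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_full_analysis(model: Model, out_dir, n: int = 1000, seed: int = 0,
                      wtps: Sequence[float] = (50_000.0, 100_000.0),
                      comparison: int = 0) -> Dict[str, Path]:
    """Run the whole pipeline and write base_case.json, tornado.csv,
    thresholds.csv, psa.csv, psa_summary.json and manifest.json into
    ``out_dir``. Returns the written paths; on any failure the files
    created by this call are removed before the error propagates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    try:
        # Base case ----------------------------------------------------
        base = run_base_case(model)
        written["base_case"] = out / "base_case.json"
        _write_json(written["base_case"], base)

        # Tornado ------------------------------------------------------
        rows = tornado(model, comparison=comparison)
        tornado_df = pd.DataFrame(
            [{"parameter": r.parameter, "delta_cost_at_low": r.delta_cost_at_low,
              "delta_cost_at_high": r.delta_cost_at_high, "swing": r.swing}
             for r in rows]
        )
        written["tornado"] = out / "tornado.csv"
        tornado_df.to_csv(written["tornado"], index=False)

        # Break-even thresholds over each parameter's own range --------
        threshold_rows = []
        for name, param in model.parameters.items():
            if param.low == param.high:
                continue
            try:
                res = find_threshold(model, name, (param.low, param.high),
                                     comparison=comparison)
            except NoThresholdError:
                continue
            threshold_rows.append({
                "parameter": name,
                "threshold": res.threshold,
                "threshold_rounded": res.threshold_rounded,
                "direction": res.direction.value,
                "bracket_low": res.bracket[0],
                "bracket_high": res.bracket[1],
            })
        written["thresholds"] = out / "thresholds.csv"
        pd.DataFrame(
            threshold_rows,
            columns=["parameter", "threshold", "threshold_rounded",
                     "direction", "bracket_low", "bracket_high"],
        ).to_csv(written["thresholds"], index=False)

        # PSA ----------------------------------------------------------
        psa = run_psa(model, n=n, seed=seed, comparison=comparison)
        psa_df = pd.DataFrame({
            "iteration": range(psa.iterations),
            "delta_cost": psa.delta_cost,
            "delta_effect": psa.delta_effect,
        })
        for w in wtps:
            psa_df[f"nmb@{w:g}"] = psa.nmb(w)
        written["psa"] = out / "psa.csv"
        psa_df.to_csv(written["psa"], index=False)
        written["psa_summary"] = out / "psa_summary.json"
        _write_json(written["psa_summary"], psa.summary(wtps))

        # Manifest -----------------------------------------------------
        written["manifest"] = out / "manifest.json"
        _write_json(written["manifest"], {
            "model": model.name,
            "model_sha256": _model_hash(model),
            "seed": seed,
            "iterations": n,
            "wtps": list(wtps),
            "comparison": list(model.comparisons[comparison]),
            "package_version": __version__,
        })
    except Exception:
        for path in written.values():
            if path.exists():
                os.remove(path)
        raise
    return written
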