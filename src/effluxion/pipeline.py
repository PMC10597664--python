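"""End-to-end orchestration: simulate → quantify → normalize → fit → compare.

A single YAML config drives a seeded virtual release experiment (solvent plus
a concentration series), the release quantification, solvent normalization,
the Hill fit, and group comparisons; every output file is recorded in a run
manifest with a content checksum so noise-off runs are reproducible
checksum-for-checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose_response import fit_hill, transform_response
from .release import (
    StimulationProtocol,
    normalize_to_solvent,
    read_fractions_csv,
    summarize_batch,
    write_fractions_csv,
)
from .simulate import DrugModel, ReleaseSimConfig, simulate_superfusion, substream
from .stats import dunns, kruskal_wallis, mann_whitney

__all__ = ["RunManifest", "run_experiment", "make_summary_tables", "validate_config"]


class PipelineError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)
    created: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_RELEASE_KEYS = {
    "n_cultures", "concentrations_uM", "noise", "condition_prefix", "sim",
}


def validate_config(cfg: dict) -> dict:
    """Schema check; raises before any stage runs."""
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a mapping")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise PipelineError("seed must be an integer")
    rel = cfg.get("release", {})
    if not isinstance(rel, dict):
        raise PipelineError("release block must be a mapping")
    unknown = set(rel) - _RELEASE_KEYS
    if unknown:
        raise PipelineError(f"unknown release config keys: {sorted(unknown)}")
    concs = rel.get("concentrations_uM", [0.0, 1.0])
    if not all(isinstance(x, (int, float)) and x >= 0 for x in concs):
        raise PipelineError("concentrations_uM must be non-negative numbers")
    if 0.0 not in [float(x) for x in concs]:
        raise PipelineError("concentration series must include a 0 (solvent) group")
    fit = cfg.get("fit", {})
    if fit.get("variant", "hill3") not in ("hill3", "fixed_nh", "fixed_imax"):
        raise PipelineError("fit.variant must be hill3, fixed_nh or fixed_imax")
    return cfg


def _condition_name(conc: float, prefix: str) -> str:
    return "solvent" if conc == 0 else f"{prefix}_{conc:g}uM"


def run_experiment(config_path: str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Run the declared stages and write a checksum manifest.

    Stages (all driven by one root seed through named substreams): simulate
    the release experiment to ``fractions.csv``; quantify per-culture ratios
    to ``summary.csv``; normalize to solvent, fit the Hill model and write
    ``fit.yaml``; write figure-style group tables via
    :func:`make_summary_tables`.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    out = Path(out_dir or cfg.get("out_dir", config_path.with_suffix("") .name + "_run"))
    out.mkdir(parents=True, exist_ok=True)

    seed = int(cfg.get("seed", 0))
    rel_cfg = cfg.get("release", {})
    n_cultures = int(rel_cfg.get("n_cultures", 12))
    concs = [float(x) for x in rel_cfg.get("concentrations_uM", [0.0, 1.0])]
    prefix = rel_cfg.get("condition_prefix", "drug")
    sim_overrides = dict(rel_cfg.get("sim", {}))
    drug_overrides = sim_overrides.pop("drug", {})
    sim = ReleaseSimConfig(
        **sim_overrides,
        drug=DrugModel(**drug_overrides),
        poisson_noise=bool(rel_cfg.get("noise", True)),
    )

    # stage 1: simulate
    series = []
    for conc in concs:
        for j in range(n_cultures):
            rng = substream(seed, "release", f"c{conc:g}", f"r{j}")
            series.append(
                simulate_superfusion(
                    sim,
                    condition=_condition_name(conc, prefix),
                    concentration_uM=conc,
                    rng=rng,
                    culture_id=f"{_condition_name(conc, prefix)}_{j:02d}",
                    batch_id=f"batch{j:02d}",
                )
            )
    fractions_path = out / "fractions.csv"
    write_fractions_csv(series, fractions_path)

    # stage 2: quantify
    protocol = sim.protocol()
    summary = summarize_batch(series, protocol)
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)

    # stage 3: normalize + fit
    fit_path = None
    positive = [c for c in concs if c > 0]
    if len(set(positive)) >= 3:
        solvent = summary.loc[
            (summary["condition"] == "solvent") & summary["evaluable"], "s2_over_s1"
        ]
        fit_c, fit_y = [], []
        for conc in positive:
            cond = _condition_name(conc, prefix)
            ratios = summary.loc[
                (summary["condition"] == cond) & summary["evaluable"], "s2_over_s1"
            ]
            normalized = normalize_to_solvent(ratios.to_numpy(), solvent.to_numpy())
            inh, _ = transform_response(normalized, "release")
            fit_c.extend([conc] * inh.size)
            fit_y.extend(inh.tolist())
        fit = fit_hill(fit_c, fit_y, variant=cfg.get("fit", {}).get("variant", "hill3"))
        fit_path = out / "fit.yaml"
        with open(fit_path, "w") as fh:
            yaml.safe_dump(fit.as_dict(), fh)

    # stage 4: figure-style tables (+ tests)
    table_path = make_summary_tables(out)

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        seed=seed,
        version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for p in [fractions_path, summary_path, fit_path, table_path]:
        if p is not None:
            manifest.files[p.name] = _sha256(p)
    manifest.write(out / "manifest.json")
    return manifest


def make_summary_tables(run_dir: str | Path) -> Path:
    """Per-condition n/mean/SEM table for S2/S1 and LL/L1 plus test results.

    Mirrors the figure-style group summaries: Kruskal-Wallis across all
    conditions followed by Dunn's comparisons of each condition vs solvent
    (Mann-Whitney when there are exactly two groups).
    """
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.csv"
    if not summary_path.exists():
        raise PipelineError(
            f"missing quantification output {summary_path}; run the quantify stage first"
        )
    df = pd.read_csv(summary_path)
    df = df[df["evaluable"].astype(bool)]
    conditions = list(dict.fromkeys(df["condition"]))
    if "solvent" in conditions:
        conditions = ["solvent"] + [c for c in conditions if c != "solvent"]
    rows = []
    for metric in ("s2_over_s1", "ll_over_l1"):
        groups = [df.loc[df["condition"] == c, metric].to_numpy() for c in conditions]
        if len(groups) >= 3:
            omnibus = kruskal_wallis(groups, conditions)
            pairwise = {
                p.group_b: p.p_adjusted
                for p in dunns(groups, conditions, comparisons="control")
            }
        elif len(groups) == 2:
            omnibus = mann_whitney(groups[0], groups[1])
            pairwise = {conditions[1]: omnibus.p_value}
        else:
            omnibus, pairwise = None, {}
        for cond, vals in zip(conditions, groups):
            rows.append(
                {
                    "metric": metric,
                    "condition": cond,
                    "n": vals.size,
                    "mean": float(np.mean(vals)) if vals.size else float("nan"),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                    if vals.size > 1
                    else float("nan"),
                    "omnibus_test": getattr(omnibus, "method", ""),
                    "omnibus_p": getattr(omnibus, "p_value", float("nan")),
                    "p_vs_solvent": pairwise.get(cond, float("nan")),
                }
            )
    table_path = run_dir / "group_tables.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)
    return table_path
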