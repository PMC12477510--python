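"""End-to-end pipeline with a reproducible run manifest.

One call wires the stages together: load (or simulate) a country table,
build maturity profiles, profile missingness, type countries, estimate the
maturity–performance association, fit the two log-expenditure regressions
and assign efficiency quadrants.  Stage outputs are CSV tables stamped with
a run digest (a SHA-256 over the configuration snapshot, input digest and
seed) so that identical runs are verifiably identical; the manifest JSON is
written last.

Stages degrade gracefully: with no performance column the association and
performance-regression stages are skipped with a warning while the maturity
stages still run; the same holds for expenditure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from ._util import is_missing
from .association import scatter_table, spearman_with_ci
from .catalog import IndicatorCatalog, default_catalog
from .country_types import PRESETS, TypeBoundaries, classify_profiles, summarize_types_by_region
from .expenditure import assign_quadrants, efficiency_report, fit_loglinear
from .index import build_profiles, profiles_to_frame, summarize_missingness
from .io import load_country_table, write_results_table
from .simulate import SyntheticConfig, generate, paper_shape_preset

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    input_digest: Optional[str]
    seed: Optional[int]
    run_digest: str = ""
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _run_digest(config: dict, input_digest: Optional[str], seed: Optional[int]) -> str:
    payload = json.dumps(
        {"config": config, "input": input_digest, "seed": seed}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(
    out_dir,
    input_path=None,
    catalog: Optional[IndicatorCatalog] = None,
    normalization: str = "minmax",
    boundaries: str = "derive",
    ci_method: str = "fisher",
    ci_level: float = 0.95,
    log_base: str = "natural",
    simulate_config: Optional[SyntheticConfig] = None,
    seed: Optional[int] = None,
) -> RunManifest:
    """Run every stage and write the output bundle under ``out_dir``.

    Either ``input_path`` (a country CSV) or ``simulate_config`` must be
    given.  Returns the manifest; raises on any stage failure with the
    stage named in the message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = catalog or default_catalog()

    if (input_path is None) == (simulate_config is None):
        raise ValueError("exactly one of input_path / simulate_config is required")

    config_snapshot = {
        "normalization": normalization,
        "boundaries": boundaries,
        "ci_method": ci_method,
        "ci_level": ci_level,
        "log_base": log_base,
        "simulate": dataclasses.asdict(simulate_config) if simulate_config else None,
        "input": str(input_path) if input_path else None,
    }
    input_digest = _sha256_file(input_path) if input_path else None
    manifest = RunManifest(
        config=config_snapshot,
        input_digest=input_digest,
        seed=seed if seed is not None else (simulate_config.seed if simulate_config else None),
    )
    manifest.run_digest = _run_digest(config_snapshot, input_digest, manifest.seed)
    stamp = f"digimat run {manifest.run_digest}"

    def _stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(time.perf_counter() - self_.t0, 4)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Timer()

    with _stage("load"):
        if simulate_config is not None:
            cfg = simulate_config if seed is None else dataclasses.replace(simulate_config, seed=seed)
            dataset = generate(cfg, catalog)
            records = dataset.records
            write_results_table(dataset.frame, out_dir / "countries.csv", comment=stamp)
            manifest.outputs["countries"] = str(out_dir / "countries.csv")
        else:
            records = load_country_table(input_path, catalog)

    with _stage("profiles"):
        profiles = build_profiles(records, catalog, normalization)
        write_results_table(profiles_to_frame(profiles, catalog), out_dir / "profiles.csv", comment=stamp)
        manifest.outputs["profiles"] = str(out_dir / "profiles.csv")

    with _stage("missingness"):
        summary = summarize_missingness(records, catalog)
        write_results_table(summary.to_frame(), out_dir / "missingness.csv", comment=stamp)
        manifest.outputs["missingness"] = str(out_dir / "missingness.csv")

    with _stage("typing"):
        preset = None if boundaries == "derive" else PRESETS[boundaries]
        typed, bounds = classify_profiles(profiles, preset)
        typed_df = pd.DataFrame(
            {
                "country_id": [t.country_id for t in typed],
                "index": [t.index for t in typed],
                "country_type": [t.country_type for t in typed],
            }
        )
        write_results_table(typed_df, out_dir / "typed.csv", comment=stamp)
        manifest.outputs["typed"] = str(out_dir / "typed.csv")
        table, means = summarize_types_by_region(typed, records)
        region_df = table.copy()
        region_df["mean_index"] = means
        write_results_table(region_df.reset_index(), out_dir / "types_by_region.csv", comment=stamp)
        manifest.outputs["types_by_region"] = str(out_dir / "types_by_region.csv")

    have_perf = any(not is_missing(r.performance_index) for r in records)
    have_exp = any(not is_missing(r.health_expenditure) for r in records)

    if have_perf:
        with _stage("association"):
            pairs = scatter_table(profiles, records, typed)
            corr = spearman_with_ci(
                pairs["index"], pairs["performance_index"],
                level=ci_level, method=ci_method, seed=manifest.seed,
            )
            assoc_df = pd.DataFrame(
                [
                    {
                        "rho": corr.rho, "ci_low": corr.ci_low, "ci_high": corr.ci_high,
                        "n": corr.n, "method": corr.method, "level": corr.level,
                    }
                ]
            )
            write_results_table(assoc_df, out_dir / "association.csv", comment=stamp)
            write_results_table(pairs, out_dir / "scatter.csv", comment=stamp)
            manifest.outputs["association"] = str(out_dir / "association.csv")
            manifest.outputs["scatter"] = str(out_dir / "scatter.csv")
    else:
        logger.warning("no performance index present: association stage skipped")
        manifest.skipped.append("association")

    if have_exp:
        with _stage("expenditure_models"):
            index_of = {p.country_id: p.index for p in profiles if p.complete}
            # intersection of complete cases across both outcomes
            ids = [
                r.country_id
                for r in records
                if r.country_id in index_of
                and not is_missing(r.health_expenditure)
                and (not have_perf or not is_missing(r.performance_index))
            ]
            expenditure = {r.country_id: r.health_expenditure for r in records}
            fit_m = fit_loglinear(
                ids, [index_of[c] for c in ids], [expenditure[c] for c in ids],
                outcome="maturity", log_base=log_base,
            )
            fits = [fit_m]
            if have_perf:
                perf = {r.country_id: r.performance_index for r in records}
                fit_p = fit_loglinear(
                    ids, [perf[c] for c in ids], [expenditure[c] for c in ids],
                    outcome="performance", log_base=log_base,
                )
                fits.append(fit_p)
            fits_df = pd.DataFrame(
                [
                    {
                        "outcome": f.outcome, "beta0": f.beta0, "beta1": f.beta1, "n": f.n,
                        "r_squared": f.r_squared, "shapiro_w": f.shapiro_w,
                        "shapiro_p": f.shapiro_p, "log_base": f.log_base,
                    }
                    for f in fits
                ]
            )
            write_results_table(fits_df, out_dir / "fits.csv", comment=stamp)
            manifest.outputs["fits"] = str(out_dir / "fits.csv")
            if have_perf:
                assignments = assign_quadrants(fit_m, fit_p)
                write_results_table(assignments, out_dir / "quadrants.csv", comment=stamp)
                manifest.outputs["quadrants"] = str(out_dir / "quadrants.csv")
    else:
        logger.warning("no health expenditure present: expenditure stage skipped")
        manifest.skipped.append("expenditure_models")
    if not have_perf and "expenditure_models" not in manifest.skipped and have_exp:
        manifest.skipped.append("performance_fit")

    manifest.write(out_dir / "manifest.json")
    manifest.outputs["manifest"] = str(out_dir / "manifest.json")
    return manifest
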