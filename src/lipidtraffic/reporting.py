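"""End-to-end run drivers: read input, run an analysis, write data products.

Every run directory gets a ``run_metadata.json`` recording the tool
version, the full configuration (threshold, network definition and hash,
seed, error form, group labels) and the input digest, so that two runs
with identical inputs and settings produce identical outputs and any
output file can be traced back to its exact configuration.  Plot-ready
products (pie-chart counts, RADAR tables) are exported as tidy CSV; no
images are rendered here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import file_sha256
from .pipeline import EnfcAnalysis, SwitchAnalysis, _resolve_network
from .simulate import SyntheticDesign, generate_cohort

__all__ = ["run_switch", "run_abundance", "run_simulate", "write_run_metadata"]

log = logging.getLogger("lipidtraffic")


def _jsonable(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    return obj


def write_run_metadata(out_dir: Path, config: dict) -> Path:
    meta = {"tool": "lipidtraffic", "version": __version__, **_jsonable(config)}
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def _read_input(
    input_path: str | Path, column_map: dict | None = None
) -> tuple[pd.DataFrame, str]:
    from .io import read_abundance_csv

    df = read_abundance_csv(input_path, column_map=column_map)
    return df, file_sha256(input_path)


def run_switch(
    input_path: str | Path,
    out_dir: str | Path,
    network=None,
    threshold: float = 0.66,
    mode: str = "v3",
    control: str | None = None,
    exposed: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    column_map: dict | None = None,
) -> SwitchAnalysis:
    """Run the switch analysis on a CSV and write its data products."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df, digest = _read_input(input_path, column_map)
    log.info("switch: %d rows from %s", len(df), input_path)

    est = SwitchAnalysis(
        network=network, threshold=threshold, mode=mode, control=control,
        exposed=exposed, n_perm=n_perm, seed=seed,
    ).fit(df)
    control_, exposed_ = est.groups_

    est.counts_.to_csv(out / "counts.csv")
    est.species_.to_csv(out / "species_dictionary.csv", index=False)
    est.edge_lists().to_csv(out / "edge_lists.csv", index=False)
    est.unique_lists().to_csv(out / "unique_lists.csv", index=False)
    status = est.comparison_.species_status.copy()
    status["class"] = status.index.map(est.species_class_)
    status.to_csv(out / "comparison_species.csv")
    if est.jaccard_ is not None:
        est.jaccard_.to_csv(out / "jaccard.csv", index=False)
    comparison = {
        "control": control_,
        "exposed": exposed_,
        "system_lost": est.comparison_.lost,
        "system_gained": est.comparison_.gained,
        "type_changes": est.comparison_.type_changes,
        "edge_changes": {f"{a}|{b}": v for (a, b), v in est.comparison_.edge_changes.items()},
        "compartment_changes": est.comparison_.compartment_changes,
        "summary_by_class": {
            str(k): v for k, v in est.comparison_.summary(est.species_class_)
            .to_dict(orient="index").items()
        },
    }
    (out / "comparison.json").write_text(json.dumps(_jsonable(comparison), indent=2) + "\n")
    if len(est.issues_):
        est.issues_.to_csv(out / "issues.csv", index=False)
        log.warning("switch: %d input issue(s) written to issues.csv", len(est.issues_))
    write_run_metadata(
        out,
        {
            "analysis": "switch",
            "input": str(input_path),
            "input_sha256": digest,
            "threshold": threshold,
            "mode": mode,
            "n_perm": n_perm,
            "seed": seed,
            "control": control_,
            "exposed": exposed_,
            "network": est.network_.to_dict(),
            "network_hash": est.network_.hash_hex,
        },
    )
    log.info("switch: wrote products to %s", out)
    return est


def run_abundance(
    input_path: str | Path,
    out_dir: str | Path,
    targets: list[str] | None = None,
    ratio_classes: list[str] | None = None,
    control: str | None = None,
    exposed: str | None = None,
    error_form: str = "half_sum_sq",
    error_scale: str = "raw",
    column_map: dict | None = None,
) -> EnfcAnalysis:
    """Run the abundance (ENFC) analysis on a CSV and write its data products."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df, digest = _read_input(input_path, column_map)
    log.info("abundance: %d rows from %s", len(df), input_path)

    est = EnfcAnalysis(
        error_form=error_form, error_scale=error_scale, control=control, exposed=exposed
    ).fit(df)
    est.class_totals_.to_csv(out / "class_totals.csv", index=False)
    est.radar_wide(est.class_totals_).to_csv(out / "class_totals_radar.csv")
    if targets:
        sp = est.species_enfc(targets)
        sp.to_csv(out / "species_enfc.csv", index=False)
        est.radar_wide(sp).to_csv(out / "species_enfc_radar.csv")
    if ratio_classes:
        ratios = pd.concat(
            [est.ratio_enfc(c) for c in ratio_classes], ignore_index=True
        )
        ratios.to_csv(out / "ratio_enfc.csv", index=False)
        est.radar_wide(ratios).to_csv(out / "ratio_enfc_radar.csv")
    write_run_metadata(
        out,
        {
            "analysis": "abundance",
            "input": str(input_path),
            "input_sha256": digest,
            "error_form": error_form,
            "error_scale": error_scale,
            "targets": targets or [],
            "ratio_classes": ratio_classes or [],
            "control": est.groups_[0],
            "exposed": est.groups_[1],
        },
    )
    log.info("abundance: wrote products to %s", out)
    return est


def run_simulate(
    out_dir: str | Path,
    design: SyntheticDesign | None = None,
    seed: int | None = None,
    **design_kwargs,
) -> tuple[Path, Path]:
    """Generate a synthetic cohort; writes cohort.csv, truth.json, design.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if design is None:
        if seed is not None:
            design_kwargs["seed"] = seed
        design = SyntheticDesign(**design_kwargs)
    table, truth = generate_cohort(design)
    cohort_path = out / "cohort.csv"
    table.to_csv(cohort_path, index=False)
    truth_payload = {
        "types": truth.types,
        "presence": {g: {s: sorted(p) for s, p in pres.items()} for g, pres in truth.presence.items()},
        "species_class": truth.species_class,
        "lost": truth.lost,
        "gained": truth.gained,
        "type_changes": truth.type_changes,
        "effects": [asdict(e) for e in truth.effects],
        "seed": truth.seed,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(_jsonable(truth_payload), indent=2) + "\n")
    design_doc = {
        "network": design.network.to_dict(),
        "n_replicates": design.n_replicates,
        "class_counts": {k: dict(v) for k, v in design.class_counts.items()},
        "dropout": design.dropout,
        "log10_mean_range": list(design.log10_mean_range),
        "log10_sd": design.log10_sd,
        "threshold": design.threshold,
        "group_labels": list(design.group_labels),
        "switches": [asdict(s) for s in design.switches],
        "effects": [asdict(e) for e in design.effects],
        "seed": design.seed,
    }
    (out / "design.yaml").write_text(yaml.safe_dump(design_doc, sort_keys=False))
    write_run_metadata(
        out,
        {
            "analysis": "simulate",
            "seed": design.seed,
            "n_species": len(truth.species_class),
            "network_hash": design.network.hash_hex,
        },
    )
    log.info("simulate: wrote %d-row cohort to %s", len(table), cohort_path)
    return cohort_path, truth_path
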