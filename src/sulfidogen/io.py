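"""Tidy time-series readers/writers, run configuration and the pipeline.

The single interchange format for microcosm chemistry is long ("tidy") CSV
with columns ``microcosm_id, treatment, generation, analyte, time_d,
value, unit`` - one row per observation, multi-analyte and multi-microcosm
by construction. Readers normalise units into the package's internal
conventions (sulfide in uM; glycerol, acetate and metals in mM; pH and
OD600 dimensionless) and collect malformed rows into a rejects report
instead of failing wholesale. Community tables travel as TSV with samples
as rows and taxa as columns.

``run_pipeline`` strings the stages together - simulate (or read) time
series, kinetics summary, reaction-energy table, titration report,
community metrics - and writes a machine-readable JSON manifest recording
inputs, seed, parameters and per-stage status. Identical config + inputs
give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioenergetics, community, geochemistry, kinetics, simulate
from .kinetics import MicrocosmSeries

__all__ = [
    "REQUIRED_COLUMNS",
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "run_pipeline",
]

REQUIRED_COLUMNS = (
    "microcosm_id",
    "treatment",
    "generation",
    "analyte",
    "time_d",
    "value",
    "unit",
)

# (internal storage unit, accepted unit -> multiplicative factor)
_UNIT_RULES: dict[str, tuple[str, dict[str, float]]] = {
    "sulfide": ("uM", {"uM": 1.0, "um": 1.0, "mM": 1e3, "mm": 1e3}),
    "sulfide_dissolved": ("uM", {"uM": 1.0, "mM": 1e3}),
    "glycerol": ("mM", {"mM": 1.0, "uM": 1e-3}),
    "acetate": ("mM", {"mM": 1.0, "uM": 1e-3}),
    "pH": ("", {"dimensionless": 1.0, "": 1.0}),
    "OD600": ("", {"dimensionless": 1.0, "": 1.0}),
}
#: atomic weights for mg/L -> mM conversion of dissolved metals
_METALS = ("Fe", "Zn", "As", "Al", "Mn", "Cu", "Ni", "Co")


def _normalise(analyte: str, value: float, unit: str) -> tuple[str, float]:
    """Return (internal analyte key, value in internal units) or raise."""
    unit = (unit or "").strip()
    if analyte in _UNIT_RULES:
        internal, factors = _UNIT_RULES[analyte]
        if unit not in factors:
            raise ValueError(f"unknown unit {unit!r} for analyte {analyte!r}")
        key = f"{analyte}_{internal}" if internal else analyte
        return key, value * factors[unit]
    if analyte in _METALS:
        from .chemistry import atomic_weights

        if unit == "mM":
            return f"{analyte}_mM", value
        if unit == "mg/L":
            return f"{analyte}_mM", value / atomic_weights()[analyte]
        raise ValueError(f"unknown unit {unit!r} for metal {analyte!r}")
    raise ValueError(f"unknown analyte {analyte!r}")


def read_timeseries(path) -> tuple[list[MicrocosmSeries], pd.DataFrame]:
    """Read a tidy time-series CSV/TSV into unit-normalised series.

    Returns (series list, rejects table). Missing required columns raise;
    rows with unknown units/analytes, non-numeric values or duplicate
    (microcosm, analyte, time) keys are rejected with a reason.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    rejects = []
    buckets: dict[tuple, dict[str, list]] = {}
    seen: set[tuple] = set()
    for idx, row in df.iterrows():
        try:
            t = float(row["time_d"])
            v = float(row["value"])
            key, value = _normalise(str(row["analyte"]), v, str(row["unit"]))
            dedup = (row["microcosm_id"], key, t)
            if dedup in seen:
                raise ValueError("duplicate (microcosm_id, analyte, time)")
            seen.add(dedup)
        except (ValueError, TypeError) as exc:
            rejects.append({**row.to_dict(), "reason": str(exc)})
            continue
        mc = (str(row["microcosm_id"]), str(row["treatment"]), int(row["generation"]))
        buckets.setdefault(mc, {}).setdefault(key, []).append((t, value))

    series = []
    for (mid, treatment, gen), analytes in buckets.items():
        arrays = {}
        for key, pts in analytes.items():
            pts.sort()
            arrays[key] = np.asarray(pts, dtype=float)
        series.append(
            MicrocosmSeries(
                microcosm_id=mid, treatment=treatment, generation=gen, analytes=arrays
            )
        )
    return series, pd.DataFrame(rejects)


def write_timeseries(series_set: list[MicrocosmSeries], path) -> None:
    """Write series back to the tidy CSV format (units in the unit column)."""
    rows = []
    for mc in series_set:
        for key, arr in mc.analytes.items():
            if "_" in key and key.rsplit("_", 1)[-1] in ("uM", "mM"):
                analyte, unit = key.rsplit("_", 1)
            else:
                analyte, unit = key, "dimensionless"
            for t, v in arr:
                rows.append(
                    {
                        "microcosm_id": mc.microcosm_id,
                        "treatment": mc.treatment,
                        "generation": mc.generation,
                        "analyte": analyte,
                        "time_d": t,
                        "value": v,
                        "unit": unit,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: Path
    seed: int = 0
    timeseries_path: Path | None = None  # simulate defaults when absent
    community_table_path: Path | None = None
    n_replicates: int = 2
    rate_threshold_uM_d: float = kinetics.DEFAULT_THRESHOLD
    stages: tuple[str, ...] = ("simulate", "thermo", "kinetics", "titrate", "community")
    titration_sulfide_mM: float = 1.0
    params_overrides: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages and write artifacts + manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "rate_threshold_uM_d": config.rate_threshold_uM_d,
        "stages": {},
        "outputs": {},
    }

    series_set: list[MicrocosmSeries] = []
    if config.timeseries_path is not None:
        series_set, rejects = read_timeseries(config.timeseries_path)
        manifest["inputs"] = {"timeseries": str(config.timeseries_path)}
        if len(rejects):
            rejects.to_csv(outdir / "rejected_rows.csv", index=False)
            manifest["outputs"]["rejected_rows"] = "rejected_rows.csv"
    elif "simulate" in config.stages:
        outputs = []
        for label, treatment in simulate.default_treatments().items():
            params = simulate.default_params(label)
            for k, v in config.params_overrides.items():
                setattr(params, k, v)
            outputs.extend(
                simulate.generate_replicate_set(
                    treatment, params, config.n_replicates, config.seed
                )
            )
        series_set = [o.to_series() for o in outputs]
        write_timeseries(series_set, outdir / "timeseries.csv")
        truths = {o.microcosm_id: o.truth for o in outputs}
        (outdir / "truth.json").write_text(json.dumps(truths, indent=2, default=float))
        manifest["stages"]["simulate"] = "complete"
        manifest["outputs"]["timeseries"] = "timeseries.csv"
        manifest["outputs"]["truth"] = "truth.json"

    if "thermo" in config.stages:
        df = bioenergetics.table2_analogue()
        df.to_csv(outdir / "reaction_energies.csv", index=False)
        manifest["stages"]["thermo"] = "complete"
        manifest["outputs"]["reaction_energies"] = "reaction_energies.csv"

    if "kinetics" in config.stages:
        if series_set:
            summary = kinetics.summarize(
                series_set, threshold=config.rate_threshold_uM_d
            )
            summary.to_csv(outdir / "kinetics_summary.csv", index=False)
            manifest["stages"]["kinetics"] = "complete"
            manifest["outputs"]["kinetics_summary"] = "kinetics_summary.csv"
        else:
            manifest["stages"]["kinetics"] = "skipped (no time series)"

    if "titrate" in config.stages:
        pool = geochemistry.MetalPool(
            {m: c for m, c in simulate.media_metal_pool().items() if m != "Al"}
        )
        before = dict(pool.dissolved)
        after, residual = geochemistry.titrate_sulfide(
            pool, config.titration_sulfide_mM * 1e-3
        )
        rows = [
            {
                "metal": m,
                "dissolved_before_mM": before[m] * 1e3,
                "dissolved_after_mM": after.dissolved[m] * 1e3,
                "removed_mM": (before[m] - after.dissolved[m]) * 1e3,
            }
            for m in before
        ]
        df = pd.DataFrame(rows)
        df["residual_sulfide_mM"] = residual * 1e3
        df.to_csv(outdir / "titration_report.csv", index=False)
        manifest["stages"]["titrate"] = "complete"
        manifest["outputs"]["titration_report"] = "titration_report.csv"

    if "community" in config.stages:
        if config.community_table_path is not None:
            table = community.AbundanceTable.read_tsv(config.community_table_path)
        else:
            table = simulate.generate_community_table(seed=config.seed)
            table.write_tsv(outdir / "community_table.tsv")
            manifest["outputs"]["community_table"] = "community_table.tsv"
        div = pd.DataFrame(
            {
                "sample": table.sample_ids,
                "group": table.groups if table.groups else "",
                "shannon_nats": [community.shannon(row) for row in table.counts],
            }
        )
        div.to_csv(outdir / "diversity.csv", index=False)
        D = community.bray_curtis_matrix(table)
        ord_res = community.pcoa(D, sample_ids=table.sample_ids)
        coords = pd.DataFrame(
            ord_res.coordinates[:, :2],
            columns=["PCo1", "PCo2"],
            index=table.sample_ids,
        )
        coords.to_csv(outdir / "pcoa_coordinates.csv", index_label="sample")
        (outdir / "pcoa_eigenvalues.json").write_text(
            json.dumps(
                {
                    "eigenvalues": ord_res.eigenvalues.tolist(),
                    "proportion_explained": ord_res.proportion_explained.tolist(),
                },
                indent=2,
            )
        )
        manifest["stages"]["community"] = "complete"
        manifest["outputs"].update(
            {
                "diversity": "diversity.csv",
                "pcoa_coordinates": "pcoa_coordinates.csv",
                "pcoa_eigenvalues": "pcoa_eigenvalues.json",
            }
        )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
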