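"""End-to-end pipeline: phantom -> classify -> embed -> transport -> dose -> plan.

Transport is the expensive stage; dose and planning are pure
post-processing, so a sweep over the canonical multiphoton-probability
presets reuses a single fluence field (the per-plan provenance carries the
shared transport run id).  The run configuration is echoed into the output
bundle for provenance, and the whole bundle is reproducible from
(config, seed).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import reporting
from .dose import DoseParams, P_MULTI_GRID, compute_ete, compute_pd_session
from .embedding import embed_tumor, tumor_mask
from .optics import OpticsTable, assign_optics
from .phantom import (LabeledVolume, PhantomRecord, compute_breast_density,
                      load_label_stack, records_to_dataframe,
                      save_labeled_volume)
from .planning import plan_treatment
from .reporting import round_half_up
from .synthetic import SyntheticParams, generate_phantom
from .transport import BeamSpec, run_transport


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    ``phantom`` is either ``{"file": path}`` or ``{"synthetic": {...}}``
    with :class:`SyntheticParams` fields plus optional ``shape``/``pitch_mm``.
    """

    phantom: dict[str, Any]
    outdir: str = "nirpdt_run"
    seed: int = 0
    n_photons: int = 10 ** 6
    internal_fresnel: bool = True
    irradiance_mW_cm2: float = 330.0
    beam_field: Any = "full"
    dose: dict[str, Any] = field(default_factory=dict)
    tumor_diameter_mm: float = 7.0
    depth_range_mm: tuple[float, float] = (15.0, 25.0)
    p_multi_grid: tuple[float, ...] = P_MULTI_GRID
    save_volumes: bool = True
    render: bool = True

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "phantom" not in d:
            raise ValueError("config must declare a phantom source")
        d = dict(d)
        if "depth_range_mm" in d:
            d["depth_range_mm"] = tuple(d["depth_range_mm"])
        if "p_multi_grid" in d:
            d["p_multi_grid"] = tuple(d["p_multi_grid"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))


def _load_phantom(cfg: RunConfig) -> tuple[LabeledVolume, dict]:
    src = cfg.phantom
    if "file" in src:
        vol = load_label_stack(src["file"])
        return vol, {"source": str(src["file"])}
    if "synthetic" in src:
        spec = dict(src["synthetic"])
        shape = tuple(spec.pop("shape", (120, 120, 120)))
        pitch = float(spec.pop("pitch_mm", 0.33))
        params = SyntheticParams(**spec)
        vol, prov = generate_phantom(params, shape, pitch)
        return vol, prov
    raise ValueError("phantom source must be {'file': ...} or {'synthetic': ...}")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Drive the full chain and write the report bundle to ``config.outdir``.

    Returns a dict with the in-memory artifacts (record, tumor spec,
    fluence, plans) plus the output paths.  An ineligible phantom yields a
    bundle with the eligibility report and no transport run.
    """
    import sys

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=1, default=str))
    bundle: dict[str, Any] = {"outdir": outdir}

    def log(stage: str, t0: float) -> None:
        print(f"[nirpdt] {stage}: {time.perf_counter() - t0:.2f} s", file=sys.stderr)

    t0 = time.perf_counter()
    try:
        vol, prov = _load_phantom(config)
    except Exception as e:  # noqa: BLE001
        raise StageError("phantom", e) from e
    log("phantom", t0)

    t0 = time.perf_counter()
    try:
        density = compute_breast_density(vol)
        record = PhantomRecord.from_density("run0", density)
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e
    log("classify", t0)

    t0 = time.perf_counter()
    try:
        vol_t, tumor = embed_tumor(vol, config.tumor_diameter_mm,
                                   config.depth_range_mm)
        record.eligible = tumor is not None
        record.tumor_depth_mm = tumor.depth_mm if tumor else None
    except Exception as e:  # noqa: BLE001
        raise StageError("embed", e) from e
    log("embed", t0)

    records_to_dataframe([record]).to_csv(outdir / "records.csv", index=False)
    bundle["record"] = record
    bundle["provenance"] = prov
    bundle["tumor"] = tumor
    if tumor is None:
        (outdir / "eligibility.json").write_text(json.dumps(
            {"eligible": False, "reason": "no duct site admits the tumor "
             "sphere within the depth range"}, indent=1))
        return bundle
    tumor.to_json(outdir / "tumor.json")

    t0 = time.perf_counter()
    try:
        optvol = assign_optics(vol_t, OpticsTable())
        beam = BeamSpec(irradiance_mW_cm2=config.irradiance_mW_cm2,
                        field=config.beam_field)
        fluence = run_transport(optvol, beam, n_photons=config.n_photons,
                                seed=config.seed,
                                internal_fresnel=config.internal_fresnel)
    except Exception as e:  # noqa: BLE001
        raise StageError("transport", e) from e
    log("transport", t0)
    bundle["fluence"] = fluence

    t0 = time.perf_counter()
    try:
        mask = tumor_mask(vol_t)
        base = DoseParams(**config.dose) if config.dose else DoseParams()
        profile = reporting.depth_profile(fluence, mask)
        profile.to_csv(outdir / "tumor_depth_profile.csv", index=False)
        summary = reporting.tumor_fluence_summary(fluence, mask)

        rows = []
        plans = {}
        for p in config.p_multi_grid:
            params = base.with_p_multi(p)
            pdv = compute_pd_session(fluence, mask, params)
            plan = plan_treatment(pdv)
            plans[p] = (pdv, plan)
            s = pdv.summary()
            rows.append({
                "p_multi": p,
                "ete_pct": round_half_up(100.0 * compute_ete(params), 1),
                "n_complete": plan.n_complete,
                "pd_session_peak": s["peak"],
                "pd_session_mean": s["mean"],
                "pd_session_sum": s["sum"],
                "fluence_run_id": pdv.provenance["fluence_run_id"],
            })
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "sessions_by_ete.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("dose/plan", e) from e
    log("dose/plan", t0)
    bundle["plans"] = plans
    bundle["tumor_fluence"] = summary

    if config.save_volumes:
        save_labeled_volume(vol_t, outdir / "phantom.nii.gz")
        fluence.save(outdir / "fluence.nii.gz")
    if config.render:
        cx = tumor.center_voxel[1]
        reporting.render_maps(
            {"labels": vol_t.labels, "fluence": fluence.phi},
            slice_axis=1, slice_index=cx, outdir=outdir / "maps",
            pitch_mm=vol_t.pitch_mm)
    (outdir / "summary.json").write_text(json.dumps({
        "density": density,
        "adjusted_density_pct": record.adjusted_density_pct,
        "birads_class": record.birads_class,
        "tumor_depth_mm": tumor.depth_mm,
        "tumor_voxels": tumor.n_voxels,
        "mean_tumor_fluence_mW_cm2": summary["mean"],
        "ledger": fluence.ledger,
        "n_complete_by_p_multi": {str(p): plans[p][1].n_complete
                                  for p in config.p_multi_grid},
    }, indent=1))
    return bundle
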