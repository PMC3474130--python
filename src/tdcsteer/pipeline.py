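"""End-to-end pipeline: phantom/head -> basis -> optimize -> stats -> reduce.

A :class:`RunConfig` names the inputs (either a phantom spec to synthesize, or
an existing head volume + montage), the optimization problem, and an output
directory.  Every output file carries provenance metadata: tool version,
config hash, and seed.  Re-running the same config reproduces the same
numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import TdcsteerError
from .forward import assemble, compute_basis
from .head_model import ConductivityTable, assemble_tensor_field
from .io import (
    read_angle_volume,
    read_label_volume,
    save_basis,
    write_label_volume,
    write_norm_nifti,
    write_result_json,
)
from .montage import Montage, standard_montage
from .optimize import CurrentSteeringModel, OptimizerSettings, ProblemSpec, reduce_pattern
from .phantoms import Blob, PhantomSpec, build_phantom, phantom_center_mm
from .roi_stats import export_table

log = logging.getLogger("tdcsteer")

__all__ = ["RunConfig", "run_pipeline", "problem_from_mapping", "phantom_spec_from_mapping"]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    out_dir: str
    head_path: str | None = None
    conductivity_path: str | None = None
    anisotropy_path: str | None = None
    montage_path: str | None = None
    phantom: dict | None = None          # inline phantom spec (alternative to head_path)
    montage_n: int = 19
    montage_area_cm2: float = 22.0
    problem: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)
    solver_tol: float = 1e-8
    reduce_k: tuple[int, ...] = ()
    report_regions: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg._source_text = Path(path).read_text()
        return cfg

    def config_hash(self) -> str:
        text = getattr(self, "_source_text", None)
        if text is None:
            text = json.dumps(
                {k: v for k, v in self.__dict__.items() if not k.startswith("_")},
                sort_keys=True, default=str,
            )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def phantom_spec_from_mapping(raw: dict) -> PhantomSpec:
    raw = dict(raw)
    for key in ("target_blobs", "avoid_blobs"):
        if key in raw:
            raw[key] = tuple(Blob(**b) for b in raw[key])
    if "shells" in raw:
        raw["shells"] = tuple((float(r), str(n)) for r, n in raw["shells"])
    return PhantomSpec(**raw)


def problem_from_mapping(raw: dict) -> ProblemSpec:
    raw = dict(raw)
    if "sign_fix" in raw and raw["sign_fix"] is not None:
        raw["sign_fix"] = tuple(raw["sign_fix"])
    return ProblemSpec(**raw)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except TdcsteerError as err:
                raise type(err)(f"[stage {name}] {err}") from err
            except FileNotFoundError as err:
                raise FileNotFoundError(f"[stage {name}] {err}") from err
            log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run phantom/basis/optimize/stats/reduce and write the artifact bundle.

    Returns a dict of output paths plus the in-memory result object.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}

    @_stage("head")
    def load_head():
        if config.phantom is not None:
            spec = phantom_spec_from_mapping({**config.phantom, "seed": config.seed})
            volume, table, aniso = build_phantom(spec)
            write_label_volume(volume, out / "head.nii.gz")
            table.to_yaml(out / "conductivities.yaml")
            origin = phantom_center_mm(spec) if spec.kind == "sphere" else None
            return volume, table, aniso, origin
        volume = read_label_volume(config.head_path)
        table = ConductivityTable.from_yaml(config.conductivity_path)
        aniso = read_angle_volume(config.anisotropy_path) if config.anisotropy_path else None
        return volume, table, aniso, None

    volume, table, aniso, origin = load_head()

    @_stage("montage")
    def get_montage():
        if config.montage_path:
            return Montage.from_json(config.montage_path, volume)
        m = standard_montage(volume, n=config.montage_n,
                             area_cm2=config.montage_area_cm2, origin_mm=origin)
        m.to_json(out / "montage.json")
        return m

    montage = get_montage()

    @_stage("basis")
    def get_basis():
        tensors = assemble_tensor_field(volume, table, aniso,
                                        default_angles=(0.0, 0.0, 0.0))
        system = assemble(volume, tensors, montage)
        basis = compute_basis(system, tol=config.solver_tol)
        save_basis(basis, out / "basis.h5", metadata=meta)
        return tensors, basis

    tensors, basis = get_basis()

    @_stage("optimize")
    def fit():
        problem = problem_from_mapping({**config.problem, "seed": config.seed})
        settings = OptimizerSettings(**config.settings)
        model = CurrentSteeringModel(basis, tensors, volume, problem)
        result = model.fit(settings)
        write_result_json(result, out / "result.json", metadata=meta)
        return result

    result = fit()

    @_stage("stats")
    def stats():
        field = result.field()
        summaries = result.region_summaries(extra_regions=config.report_regions)
        export_table(summaries, out / "stats.csv")
        with open(out / "stats.csv", "a") as fh:
            fh.write(f"# tool_version={__version__} config_hash={meta['config_hash']} "
                     f"seed={meta['seed']}\n")
        write_norm_nifti(field, out / "norm.nii.gz")
        return summaries

    summaries = stats()

    @_stage("reduce")
    def reduced():
        rows = {}
        for k in config.reduce_k:
            Xk, remainder = reduce_pattern(result.X, int(k))
            rows[int(k)] = {
                "weights_mA": Xk.values.tolist(),
                "extracranial_remainder_mA": remainder,
            }
        if rows:
            with open(out / "reduced.json", "w") as fh:
                json.dump({"provenance": meta, "patterns": rows}, fh, indent=1)
        return rows

    reduced_patterns = reduced()

    return {
        "out_dir": str(out),
        "result": result,
        "summaries": summaries,
        "reduced": reduced_patterns,
        "paths": {
            "basis": str(out / "basis.h5"),
            "result": str(out / "result.json"),
            "stats": str(out / "stats.csv"),
            "norm": str(out / "norm.nii.gz"),
        },
    }
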