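"""Configuration and the multi-stage analysis pipeline.

A :class:`RunConfig` (YAML-serialisable) names the stages to run and their
parameters; :func:`run_pipeline` executes them in the fixed order
mechanics -> helix -> profile -> compare -> cavities, writes per-stage
artifacts plus one JSON report, and is deterministic for fixed seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import yaml

from . import cavities as cav
from . import compare as cmp
from . import helical, io, profiles, synthetic
from .exceptions import FibrilMetricsError, InputError
from .mechanics import WormLikeChainModel

logger = logging.getLogger("fibrilmetrics")

STAGE_ORDER = ("mechanics", "helix", "profile", "compare", "cavities")


def _package_version() -> str:
    try:
        return version("fibrilmetrics")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """Pipeline configuration; unset stages are skipped."""

    output_dir: str = "fibrilmetrics_out"
    seed: int = 42
    mechanics: dict | None = None
    helix: dict | None = None
    profile: dict | None = None
    compare: dict | None = None
    cavities: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InputError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def input_paths(self) -> list[Path]:
        paths = []
        for stage in STAGE_ORDER:
            cfg = getattr(self, stage)
            if not cfg:
                continue
            for key in ("traces", "fasta", "model", "native", "fibril",
                        "predictors_dir", "structure"):
                if cfg.get(key):
                    paths.append(Path(cfg[key]))
        return paths


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_mechanics(cfg: dict, outdir: Path, seed: int) -> dict:
    if cfg.get("traces"):
        traces = io.read_traces(cfg["traces"])
    else:
        syn = cfg.get("synthetic", {})
        traces = synthetic.generate_trace_ensemble(
            persistence_length=syn.get("persistence_length", 6.7),
            n=syn.get("n", 124),
            length_range=tuple(syn.get("length_range", (1.0, 8.0))),
            step=syn.get("step", 0.02),
            seed=syn.get("seed", seed))
        io.write_traces(traces, outdir / "traces.csv")
    model = WormLikeChainModel.from_traces(
        traces, temperature_k=cfg.get("temperature", 300.0))
    res = model.fit(n_bootstrap=cfg.get("n_bootstrap", 1000),
                    seed=cfg.get("seed", seed))
    (outdir / "mechanics_summary.txt").write_text(res.summary() + "\n")
    return res.to_dict()


def _stage_helix(cfg: dict, outdir: Path, seed: int) -> dict:
    sym = helical.HelicalSymmetry(rise=cfg.get("rise", 4.8),
                                  twist=cfg.get("twist", -0.58))
    layer = synthetic.generate_beta_arch_layer(
        n_residues=cfg.get("n_residues", 91),
        spacing=cfg.get("spacing", 3.8))
    stack = helical.build_stack(layer, sym, n_layers=cfg.get("layers", 5))
    io.write_structure(stack, outdir / "stack.pdb")
    pitch, crossover, hand = helical.pitch_and_crossover(sym)
    est = helical.estimate_symmetry_from_model(stack)
    contacts = helical.interlayer_contacts(stack, cutoff=cfg.get("cutoff", 4.5))
    return {
        "rise_A": sym.rise, "twist_deg": sym.twist,
        "pitch_A": pitch, "crossover_A": crossover, "handedness": hand,
        "estimated_rise_A": est.symmetry.rise,
        "estimated_twist_deg": est.symmetry.twist,
        "estimate_rmsd_A": est.rmsd,
        "n_interlayer_contacts": int(len(contacts.at_offset(1))),
    }


def _stage_profile(cfg: dict, outdir: Path, seed: int) -> dict:
    if cfg.get("fasta"):
        records = io.read_fasta(cfg["fasta"])
        if len(records) < 2:
            raise InputError("profile stage needs patient and germline records")
        (patient, germline), *_ = [tuple(records.values())[:2]]
    else:
        germline = synthetic.GERMLINE_TEMPLATE_SYNTHETIC
        patient = synthetic.patient_sequence_synthetic()
    window = cfg.get("window", 1)
    hydro = profiles.hydropathy_profile(patient, window=window)
    muts = profiles.list_mutations(patient, germline)
    report: dict = {
        "n_residues": len(patient),
        "hydropathy_window": window,
        "hydropathy_mean": float(hydro.mean()),
        "mutations": [m.label for m in muts],
        "n_mutations": len(muts),
    }
    if cfg.get("predictors_dir"):
        pdir = Path(cfg["predictors_dir"])
        hit_sets = [profiles.parse_predictor_output(pdir / f"{name}.tsv", name,
                                                    len(patient))
                    for name in profiles.PREDICTOR_NAMES]
        profile = profiles.consensus_amyloid_score(hit_sets, patient)
        profile.to_frame().to_csv(outdir / "amyloid_score.csv", index=False)
        report["amyloid_score_max"] = int(profile.scores.max())
        report["n_score5_residues"] = int((profile.scores == 5).sum())
    else:
        report["packing_density_hits"] = sorted(
            profiles.packing_density_scan(patient).positions)
        report["aggrescan_hits"] = sorted(
            profiles.aggrescan_scan(patient).positions)
    return report


def _stage_compare(cfg: dict, outdir: Path, seed: int) -> dict:
    native = io.read_structure(cfg["native"])
    fibril = io.read_structure(cfg["fibril"])
    segs = cfg.get("segments", [[16, 23], [86, 93]])
    rep = cmp.switch_report(native, fibril, tuple(segs[0]), tuple(segs[1]))
    out = rep.to_dict()
    for name, model in (("native", native), ("fibril", fibril)):
        try:
            d, bonded = cmp.disulfide_geometry(model)
            out[f"disulfide_{name}"] = {"distance_A": d, "bonded": bonded}
        except FibrilMetricsError as exc:
            out[f"disulfide_{name}"] = {"error": str(exc)}
    return out


def _stage_cavities(cfg: dict, outdir: Path, seed: int) -> dict:
    if cfg.get("model"):
        model = io.read_structure(cfg["model"])
    else:
        phantom = cfg.get("phantom", {})
        spec = synthetic.PhantomSpec(
            void_radius=phantom.get("void_radius", 3.0),
            shell_thickness=phantom.get("shell_thickness", 6.0),
            atom_spacing=phantom.get("atom_spacing", 1.0))
        model = synthetic.generate_cavity_phantom(spec)
    found = cav.find_cavities(model, spacing=cfg.get("spacing", 0.5),
                              probe=cfg.get("probe", 1.4),
                              min_volume=cfg.get("min_volume", 20.0))
    found = [cav.cavity_polarity_report(model, c,
                                        lining_cutoff=cfg.get("lining_cutoff", 4.5))
             for c in found]
    if found:
        io.write_structure(cav.cavities_to_pseudo_atoms(found),
                           outdir / "cavity_voxels.pdb")
    return {
        "n_cavities": len(found),
        "cavities": [{"label": c.label, "volume_A3": c.volume,
                      "polarity": c.polarity_class,
                      "polar_fraction": c.polar_fraction,
                      "n_lining_residues": int(len(c.lining_residues))}
                     for c in found],
    }


_STAGES = {"mechanics": _stage_mechanics, "helix": _stage_helix,
           "profile": _stage_profile, "compare": _stage_compare,
           "cavities": _stage_cavities}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in order; returns the report dict.

    Missing input files fail validation before any stage runs. A stage
    failure is recorded under ``errors`` and later stages still run; the
    caller decides the exit status from ``report['errors']``.
    """
    missing = [str(p) for p in config.input_paths() if not p.exists()]
    if missing:
        raise InputError(f"input paths do not exist: {missing}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"package_version": _package_version(),
                    "seed": config.seed, "stages": {}, "errors": {}}
    for stage in STAGE_ORDER:
        cfg = getattr(config, stage)
        if cfg is None:
            continue
        logger.info("running stage %s (seed=%d)", stage, config.seed)
        try:
            report["stages"][stage] = _STAGES[stage](dict(cfg), outdir,
                                                     config.seed)
        except FibrilMetricsError as exc:
            logger.error("stage %s failed: %s", stage, exc)
            report["errors"][stage] = str(exc)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
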