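"""Workflow orchestration: neutron (inelastic + elastic) and MD analyses.

Configurations are plain YAML mappings; reports are JSON + TSV so runs can
be diffed directly. Every stage records its inputs and failures; a failed
stage marks the bundle partial and downstream stages are skipped with the
cause recorded.
"""

from __future__ import annotations

import glob as globmod
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dispersion as disp
from . import lamellar, lateral, spectral
from .scans import read_frames, read_reflectivity, read_scan

__all__ = ["RunConfig", "run_neutron_workflow", "run_md_workflow"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration."""

    workflow: str                   # neutron | md
    options: dict = field(default_factory=dict)
    seed: int = 0
    outdir: Path = Path("membranekit_out")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(workflow=raw.pop("workflow"),
                   seed=int(raw.pop("seed", 0)),
                   outdir=Path(raw.pop("outdir", "membranekit_out")),
                   options=raw)

    def validate_paths(self, paths) -> list[Path]:
        out = []
        for pattern in paths:
            hits = sorted(globmod.glob(str(pattern)))
            if not hits:
                raise FileNotFoundError(f"no input matches {pattern!r}")
            out.extend(Path(h) for h in hits)
        return out


class _Json(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)


def _write_json(payload, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, cls=_Json, sort_keys=True))


def _fit_sample_scans(name: str, cfg: RunConfig, report: dict):
    opts = cfg.options
    sample = opts["samples"][name]
    results = []
    for path in cfg.validate_paths(sample.get("constant_q_scans", [])):
        scan = read_scan(path)
        selection = spectral.sequential_f_test(
            scan, alpha=float(opts.get("alpha", 0.025)),
            df_policy=opts.get("df_policy", "standard"),
            n_restarts=int(opts.get("n_restarts", 4)))
        report.setdefault("scans", {})[str(path)] = {
            "chosen_k": selection.chosen_k,
            "f_chi": selection.f_chi_values,
            "f_critical": selection.f_critical_values,
            "chi2": [f.chi2 for f in selection.fits],
        }
        results.append(selection.chosen_fit)
    for path in cfg.validate_paths(sample.get("constant_e_scans", [])):
        scan = read_scan(path)
        res = spectral.fit_constant_e_scan(
            scan, n_peaks=int(opts.get("n_e_peaks", 2)))
        report.setdefault("scans", {})[str(path)] = {
            "centers": res.centers, "chi2": res.chi2,
            "converged": res.converged}
        results.append(res)
    return results


def run_neutron_workflow(config: RunConfig) -> dict:
    """Fit all scans, build dispersions, fit branch minima, compare samples.

    Returns the report bundle (also written to ``outdir``): per-scan model
    selection, per-branch quadratic parameters per sample, and — when two
    samples are configured — a parameter comparison table.
    """
    opts = config.options
    report: dict = {"workflow": "neutron", "seed": config.seed,
                    "partial": False, "samples": {}}
    anchors = opts.get("anchors") or disp.DEFAULT_ANCHORS
    fit_range = tuple(opts.get("fit_range", (1.0, 2.0)))
    branch_tables: dict[str, dict] = {}
    widths: dict[str, dict] = {}
    for name in opts["samples"]:
        sample_report: dict = {}
        try:
            fits = _fit_sample_scans(name, config, sample_report)
            points = disp.collect_points(fits)
            disp.assign_branches(points, anchors,
                                 cutoff=opts.get("assign_cutoff"))
            sample_report["points"] = [
                {"q_par": p.q_par, "energy": p.energy,
                 "energy_err": p.energy_err, "branch": p.branch,
                 "source": p.source} for p in points]
            fits_by_branch = {}
            widths[name] = {}
            for branch in disp.BRANCHES:
                try:
                    bf = disp.fit_branch_minimum(points, fit_range=fit_range,
                                                 branch=branch)
                except ValueError as exc:
                    sample_report.setdefault("branch_failures", {})[branch] \
                        = str(exc)
                    continue
                fits_by_branch[branch] = bf
                sample_report.setdefault("branches", {})[branch] = {
                    "alpha": bf.alpha, "q0": bf.q0, "omega0": bf.omega0,
                    "bse": bf.bse, "n_points": bf.n_points}
                try:
                    w, werr = disp.width_at_minimum(points, bf)
                    widths[name][branch] = (w, werr)
                    sample_report["branches"][branch]["width"] = w
                    sample_report["branches"][branch]["width_err"] = werr
                except ValueError:
                    pass
            branch_tables[name] = fits_by_branch
        except Exception as exc:            # stage failure -> partial bundle
            report["partial"] = True
            sample_report["error"] = str(exc)
            log.exception("sample %s failed", name)
        report["samples"][name] = sample_report
    if len(branch_tables) == 2:
        name_a, name_b = list(branch_tables)
        comparison: dict = {}
        for branch in disp.BRANCHES:
            if branch in branch_tables[name_a] and \
                    branch in branch_tables[name_b]:
                rep = disp.compare_branch_parameters(
                    branch_tables[name_a][branch],
                    branch_tables[name_b][branch])
                comparison[branch] = {
                    c.name: {"a": c.value_a, "b": c.value_b, "z": c.z,
                             "significant": c.significant}
                    for c in rep.comparisons}
                wa = widths.get(name_a, {}).get(branch)
                wb = widths.get(name_b, {}).get(branch)
                if wa and wb and all(np.isfinite([wa[1] or np.nan,
                                                  wb[1] or np.nan])):
                    z = abs(wa[0] - wb[0]) / float(np.hypot(wa[1], wb[1]))
                    comparison[branch]["width"] = {
                        "a": wa[0], "b": wb[0], "z": z,
                        "significant": z > 1.96}
        report["comparison"] = {"a": name_a, "b": name_b,
                                "branches": comparison}
    _write_json(report, config.outdir / "neutron_report.json")
    return report


def run_elastic_analysis(qz_path, phases, inplane_path=None,
                         outdir: Path | None = None) -> dict:
    """Bragg series -> d_z, SLD profile, d_HH; optional in-plane q_T/A_T."""
    scan = read_reflectivity(qz_path)
    peaks = lamellar.find_bragg_peaks(scan)
    profile = lamellar.reconstruct_sld(peaks, phases)
    summary = {"d_z": peaks.d_z,
               "orders": peaks.orders,
               "intensities": peaks.intensities,
               "d_hh": lamellar.head_head_spacing(profile)}
    if inplane_path is not None:
        inplane = lamellar.fit_inplane_peak(read_scan(inplane_path))
        summary.update({"q_t": inplane.q_t, "q_t_err": inplane.q_t_err,
                        "a_t": inplane.a_t})
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "sld.tsv",
                   np.column_stack([profile.z, profile.rho]),
                   delimiter="\t", header="z_A\trho_rel")
        _write_json(summary, outdir / "elastic_summary.json")
    return summary


_MD_TASKS = ("rdf", "apl", "gauche", "density", "contacts")


def run_md_workflow(config: RunConfig) -> dict:
    """Run the configured lateral-structure analyses on membrane frames."""
    opts = config.options
    frames = read_frames(config.validate_paths(opts["frames"]))
    tasks = opts.get("tasks", list(_MD_TASKS))
    report: dict = {"workflow": "md", "seed": config.seed, "partial": False,
                    "n_frames": len(frames), "tasks": {}}
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    has_asa = any("ASA" in frame.resnames for frame in frames)
    for task in tasks:
        if task not in _MD_TASKS:
            raise ValueError(f"unknown task {task!r}")
        try:
            if task == "rdf":
                r_max = float(opts.get("r_max", 25.0))
                rdf = lateral.lateral_rdf(
                    frames, {"resname": "DMPC", "name_prefix": "C"},
                    {"resname": "DMPC", "name_prefix": "C"}, r_max=r_max,
                    bin_width=float(opts.get("rdf_bin", 0.2)))
                np.savetxt(outdir / "rdf_dmpc_dmpc.tsv",
                           np.column_stack([rdf.r, rdf.g]), delimiter="\t",
                           header="r_A\tg")
                report["tasks"]["rdf"] = {"first_peak": rdf.first_peak(),
                                          "file": "rdf_dmpc_dmpc.tsv"}
            elif task == "apl":
                maps = lateral.grid_area_map(
                    frames[0], policy=opts.get("apl_policy", "chol_as_lipid"))
                dmpc = [a for m in maps.values()
                        for a in m.areas_for("DMPC").values()]
                report["tasks"]["apl"] = {
                    "mean_dmpc_area": float(np.mean(dmpc)),
                    "n_dmpc": len(dmpc)}
            elif task == "gauche":
                if not has_asa:
                    report["tasks"]["gauche"] = {
                        "skipped": "no ASA in frames"}
                    continue
                prof = lateral.distance_resolved_gauche(
                    frames, stride=int(opts.get("stride", 50)))
                np.savetxt(outdir / "gauche_profile.tsv",
                           np.column_stack([prof.bin_centers, prof.values,
                                            prof.counts]),
                           delimiter="\t", header="r_A\tgauche\tn")
                report["tasks"]["gauche"] = {"file": "gauche_profile.tsv"}
            elif task == "density":
                prof = lateral.density_profile(
                    frames, groups={"DMPC": {"resname": "DMPC"},
                                    "CHOL": {"resname": "CHOL"},
                                    "ASA": {"resname": "ASA"},
                                    "SOL": {"resname": "SOL"}}
                    if has_asa else
                    {"DMPC": {"resname": "DMPC"},
                     "SOL": {"resname": "SOL"}},
                    weighting=opts.get("weighting", "electron"))
                cols = [prof.z] + [prof.densities[g] for g in prof.densities]
                np.savetxt(outdir / "density_profile.tsv",
                           np.column_stack(cols), delimiter="\t",
                           header="z_A\t" + "\t".join(prof.densities))
                report["tasks"]["density"] = {"file": "density_profile.tsv",
                                              "groups": list(prof.densities)}
            elif task == "contacts":
                if not has_asa:
                    report["tasks"]["contacts"] = {
                        "skipped": "no ASA in frames"}
                    continue
                stats = lateral.contact_fraction(
                    frames, {"resname": "CHOL"}, {"resname": "ASA"},
                    cutoff=float(opts.get("contact_cutoff", 3.5)))
                report["tasks"]["contacts"] = {
                    "any_contact_fraction": stats.any_contact_fraction,
                    "n_pairs": len(stats.pair_fractions)}
        except Exception as exc:
            report["partial"] = True
            report["tasks"][task] = {"error": str(exc)}
            log.exception("task %s failed", task)
    _write_json(report, outdir / "md_report.json")
    return report
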