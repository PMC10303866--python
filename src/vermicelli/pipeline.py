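"""Pipeline stages and the end-to-end preset comparison.

Each stage is a deterministic function of an :class:`AnalysisConfig`
(all randomness flows through explicit seeds); stages write their
outputs plus a structured JSON log of the parameters used. The CLI in
:mod:`vermicelli.cli` is a thin wrapper over this registry.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp
from . import hic, images, kinetics, tads
from .config import AnalysisConfig
from .errors import UsageError
from .io import (
    FluorTrace,
    make_bins,
    read_bed,
    read_bins,
    read_contact_matrix,
    read_image,
    read_trace,
    read_track,
    write_bed,
    write_bins,
    write_contact_matrix,
    write_image,
    write_trace,
    write_track,
)
from .simulate import (
    FrapSimParams,
    HiCSimParams,
    ImageSimParams,
    control_preset,
    oe_preset,
    simulate_contact_map,
    simulate_frap_trace,
    simulate_ifrap_trace,
    simulate_nucleus_image,
)

logger = logging.getLogger("vermicelli")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default,
                               sort_keys=True) + "\n")


def _log_params(stage: str, params: dict, out_dir: Path) -> None:
    logger.info("stage %s parameters: %s", stage, params)
    _write_json({"stage": stage, "parameters": params},
                out_dir / f"{stage}.log.json")


# ---------------------------------------------------------------------------
# simulation stages


def stage_simulate_hic(cfg: AnalysisConfig, out_dir: Path, *,
                       preset: str | None = None, **_) -> dict:
    p = cfg["simulate_hic"]
    seed = cfg["global"]["seed"]
    kwargs = dict(n_bins=p["n_bins"], bin_size=p["bin_size"],
                  depth=p["depth"], tad_size=p["tad_size"],
                  block_size=p["block_size"],
                  corner_width=p["corner_width"],
                  expected_only=p["expected_only"], seed=seed)
    if preset == "control":
        params = control_preset(**kwargs)
    elif preset in ("oe", "oe-like"):
        params = oe_preset(**kwargs)
    else:
        params = HiCSimParams(alpha=p["alpha"], epsilon=p["epsilon"],
                              beta=p["beta"], gamma=p["gamma"],
                              inter_tad_boost=p["inter_tad_boost"], **kwargs)
    matrix, truth = simulate_contact_map(params)
    write_contact_matrix(matrix, out_dir / "matrix.triplet.txt")
    write_bins(matrix.bins, out_dir / "bins.bed")
    write_track(truth["labels"].astype(float), matrix.bins,
                out_dir / "truth_labels.bedgraph")
    tad_iv = np.asarray(truth["tads"]) * params.bin_size
    write_bed(pd.DataFrame({"chrom": "chrS", "start": tad_iv[:, 0],
                            "end": np.minimum(tad_iv[:, 1],
                                              matrix.bins.ends[-1])}),
              out_dir / "truth_tads.bed")
    _log_params("simulate-hic", dataclasses.asdict(params) | {
        "preset": preset,
        "compartment_labels": None, "tad_boundaries": None}, out_dir)
    return {"matrix": out_dir / "matrix.triplet.txt",
            "bins": out_dir / "bins.bed"}


def stage_simulate_image(cfg: AnalysisConfig, out_dir: Path, **_) -> dict:
    p = cfg["simulate_image"]
    params = ImageSimParams(seed=cfg["global"]["seed"], **{
        k: p[k] for k in ("height", "width", "pixel_size", "mode", "n_fibers",
                          "bead_spacing", "spacing_jitter_sd",
                          "bead_amplitude", "background", "psf_sigma",
                          "nucleolus_count", "nucleolus_radius", "noise",
                          "gaussian_sd")})
    img, beads, fiber = simulate_nucleus_image(params)
    write_image(img, out_dir / "image.tif")
    write_image(img.nucleus_mask.astype(np.float32), out_dir / "nucleus_mask.tif")
    write_image(img.exclusion_mask.astype(np.float32),
                out_dir / "exclusion_mask.tif")
    pd.DataFrame({"y": beads[:, 0], "x": beads[:, 1], "fiber": fiber}
                 ).to_csv(out_dir / "truth_beads.csv", index=False)
    _log_params("simulate-image", dataclasses.asdict(params), out_dir)
    return {"image": out_dir / "image.tif"}


def stage_simulate_frap(cfg: AnalysisConfig, out_dir: Path, **_) -> dict:
    p = cfg["simulate_frap"]
    seed = cfg["global"]["seed"]
    base = {k: p[k] for k in ("A", "B", "tauA", "tauB", "dt", "n_pre",
                              "n_post", "acquisition_bleach_rate", "noise_sd",
                              "ifrap_tau", "ifrap_plateau",
                              "ifrap_amplitude")}
    frap = simulate_frap_trace(FrapSimParams(mode="frap", seed=seed, **base))
    ifrap = simulate_ifrap_trace(FrapSimParams(mode="ifrap", seed=seed + 1,
                                               **base))
    write_trace(frap, out_dir / "frap_trace.csv")
    write_trace(ifrap, out_dir / "ifrap_trace.csv")
    _log_params("simulate-frap", base | {"seed": seed}, out_dir)
    return {"frap": out_dir / "frap_trace.csv",
            "ifrap": out_dir / "ifrap_trace.csv"}


# ---------------------------------------------------------------------------
# image stages


def stage_heterogeneity(cfg: AnalysisConfig, out_dir: Path, *,
                        image: str, **_) -> dict:
    p = cfg["heterogeneity"]
    img = read_image(image, pixel_size=cfg["simulate_image"]["pixel_size"])
    result = images.heterogeneity_level(img, box=p["box"], stride=p["stride"],
                                        target_mean=p["target_mean"])
    _write_json(dataclasses.asdict(result), out_dir / "heterogeneity.json")
    _log_params("heterogeneity", p | {"image": str(image)}, out_dir)
    return {"report": out_dir / "heterogeneity.json"}


def stage_beads(cfg: AnalysisConfig, out_dir: Path, *, image: str, **_) -> dict:
    p = cfg["beads"]
    img = read_image(image, pixel_size=cfg["simulate_image"]["pixel_size"])
    beads = images.detect_beads(img, min_separation=p["min_separation"],
                                threshold=p["threshold"],
                                psf_sigma=p["psf_sigma"],
                                expected_spacing=p["expected_spacing"])
    summary = images.bead_spacings(beads)
    pd.DataFrame({"y": beads.coords[:, 0], "x": beads.coords[:, 1],
                  "fiber": beads.fiber, "order": beads.order}
                 ).to_csv(out_dir / "beads.csv", index=False)
    pd.DataFrame({"spacing_um": summary["spacings"]}
                 ).to_csv(out_dir / "spacings.csv", index=False)
    _write_json({"n_beads": len(beads.coords),
                 "mean_spacing_um": summary["mean"],
                 "median_spacing_um": summary["median"]},
                out_dir / "beads.json")
    _log_params("beads", p | {"image": str(image)}, out_dir)
    return {"beads": out_dir / "beads.csv"}


def stage_coloc(cfg: AnalysisConfig, out_dir: Path, *, image: str,
                image2: str, **_) -> dict:
    px = cfg["simulate_image"]["pixel_size"]
    a, b = read_image(image, px), read_image(image2, px)
    r = images.pearson_colocalization(a, b)
    _write_json({"pearson_r": r}, out_dir / "coloc.json")
    _log_params("coloc", {"image": str(image), "image2": str(image2)}, out_dir)
    return {"report": out_dir / "coloc.json"}


def stage_clusters(cfg: AnalysisConfig, out_dir: Path, *, image: str,
                   **_) -> dict:
    p = cfg["clusters"]
    img = read_image(image, pixel_size=cfg["simulate_image"]["pixel_size"])
    cs = images.segment_clusters(img, threshold=p["threshold"],
                                 min_diameter=p["min_diameter"])
    pd.DataFrame({"area_um2": cs.areas_um2, "pixels": cs.pixel_counts}
                 ).to_csv(out_dir / "clusters.csv", index=False)
    _log_params("clusters", p | {"image": str(image)}, out_dir)
    return {"clusters": out_dir / "clusters.csv"}


# ---------------------------------------------------------------------------
# kinetics stages


def stage_frap_fit(cfg: AnalysisConfig, out_dir: Path, *, traces: str,
                   **_) -> dict:
    trace = read_trace(traces)
    corrected = kinetics.correct_photobleaching(trace)
    norm = kinetics.normalize_frap(corrected)
    post = slice(trace.pre_bleach_count, None)
    t = trace.times[post] - trace.times[trace.pre_bleach_count]
    fit = kinetics.fit_double_exponential(t, norm[post])
    _write_json(dataclasses.asdict(fit), out_dir / "frap_fit.json")
    from .simulate import frap_recovery
    pd.DataFrame({"time_s": t, "normalized": norm[post],
                  "fitted": frap_recovery(t, fit.A, fit.tauA, fit.B, fit.tauB)}
                 ).to_csv(out_dir / "frap_curve.csv", index=False)
    _log_params("frap-fit", {"traces": str(traces)}, out_dir)
    return {"fit": out_dir / "frap_fit.json"}


def stage_ifrap(cfg: AnalysisConfig, out_dir: Path, *, traces: str,
                **_) -> dict:
    paths = str(traces).split(",")
    norms = []
    times = None
    for p in paths:
        tr = read_trace(p)
        norms.append(kinetics.normalize_ifrap(tr))
        times = tr.times
    df = pd.DataFrame({"time_s": times})
    for k, v in enumerate(norms):
        df[f"trace_{k}"] = v
    if len(norms) >= 2:
        mean, sd = kinetics.aggregate_traces(norms)
        df["mean"], df["sd"] = mean, sd
    df.to_csv(out_dir / "ifrap_normalized.csv", index=False)
    _log_params("ifrap", {"traces": str(traces)}, out_dir)
    return {"normalized": out_dir / "ifrap_normalized.csv"}


# ---------------------------------------------------------------------------
# Hi-C stages


def _load_matrix(cfg: AnalysisConfig, matrix: str, bins: str):
    gb = read_bins(bins)
    dialect = "dense-tsv" if str(matrix).endswith(".tsv") else "triplet"
    return read_contact_matrix(matrix, gb, dialect=dialect)


def stage_hic_stats(cfg: AnalysisConfig, out_dir: Path, *, matrix: str,
                    bins: str, **_) -> dict:
    p = cfg["hic_stats"]
    m = _load_matrix(cfg, matrix, bins)
    balanced = hic.ice_balance(m, tol=p["balance_tol"], max_iter=p["max_iter"],
                               min_coverage_mad=p["min_coverage_mad"])
    np.savetxt(out_dir / "balanced.tsv", balanced.balanced(), delimiter="\t",
               fmt="%.8g")
    curve = hic.contact_probability(balanced,
                                    geometric_factor=p["geometric_factor"])
    pd.DataFrame({"distance_bp": curve.centers_bp,
                  "distance_bins": curve.centers_bins,
                  "probability": curve.probabilities,
                  "n_pairs": curve.pair_counts}
                 ).to_csv(out_dir / "ps_curve.csv", index=False)
    report = {"total_contacts": m.total,
              "n_valid_bins": int(balanced.valid_bins.sum()),
              "converged": bool(getattr(balanced, "converged", True))}
    n = m.n_bins
    if n >= 20:
        report["ps_slope"] = hic.ps_slope(curve, 5, min(200, n // 2))
    if len(set(map(str, m.bins.chroms))) >= 2:
        report["trans_ratio"] = hic.trans_ratio(m)
    _write_json(report, out_dir / "hic_stats.json")
    _log_params("hic-stats", p | {"matrix": str(matrix)}, out_dir)
    return {"report": out_dir / "hic_stats.json"}


def stage_compartments(cfg: AnalysisConfig, out_dir: Path, *, matrix: str,
                       bins: str, track: str | None = None, **_) -> dict:
    p = cfg["compartments"]
    hp = cfg["hic_stats"]
    m = _load_matrix(cfg, matrix, bins)
    balanced = hic.ice_balance(m, tol=hp["balance_tol"])
    orientation = read_track(track, m.bins) if track else None
    profile = comp.compute_pc1(balanced, orientation)
    write_track(profile.pc1, m.bins, out_dir / "pc1.bedgraph")
    lab = profile.labels
    det = lab != 0
    write_bed(pd.DataFrame({"chrom": m.bins.chroms[det],
                            "start": m.bins.starts[det],
                            "end": m.bins.ends[det],
                            "name": np.where(lab[det] == 1, "A", "B")}),
              out_dir / "labels.bed")
    oe = hic.observed_over_expected(balanced)
    grid = comp.saddle(oe, profile, n_quantiles=p["n_quantiles"])
    np.savetxt(out_dir / "saddle.csv", grid, delimiter=",", fmt="%.8g")
    ratio = comp.mixing_ratio(balanced, profile)
    _write_json({"mixing_ratio": ratio, "degenerate": profile.degenerate,
                 "oriented": profile.oriented}, out_dir / "compartments.json")
    _log_params("compartments", p | {"matrix": str(matrix)}, out_dir)
    return {"pc1": out_dir / "pc1.bedgraph"}


def stage_tads(cfg: AnalysisConfig, out_dir: Path, *, matrix: str, bins: str,
               **_) -> dict:
    p = cfg["tads"]
    hp = cfg["hic_stats"]
    m = _load_matrix(cfg, matrix, bins)
    balanced = hic.ice_balance(m, tol=hp["balance_tol"])
    profile = tads.insulation_score(balanced, window=p["window"])
    profile = tads.call_boundaries(profile, delta_window=p["delta_window"],
                                   min_strength=p["min_strength"])
    write_track(profile.score, m.bins, out_dir / "insulation.bedgraph")
    bs = m.bin_size
    write_bed(pd.DataFrame({"chrom": "chrS",
                            "start": profile.boundaries * bs,
                            "end": (profile.boundaries + 1) * bs,
                            "name": "boundary",
                            "score": profile.boundary_strength}),
              out_dir / "boundaries.bed")
    ts = tads.tads_from_boundaries(profile.boundaries, m.bins)
    write_bed(pd.DataFrame({"chrom": "chrS", "start": ts.intervals[:, 0],
                            "end": ts.intervals[:, 1]}),
              out_dir / "tads.bed")
    scores = tads.tad_score(balanced, ts)
    scores.to_csv(out_dir / "tad_scores.csv", index=False)
    stats = tads.tad_length_stats(ts, long_threshold=p["long_threshold"])
    _write_json({k: v for k, v in stats.items() if k != "lengths"},
                out_dir / "tad_stats.json")
    _log_params("tads", p | {"matrix": str(matrix)}, out_dir)
    return {"tads": out_dir / "tads.bed"}


def stage_ata(cfg: AnalysisConfig, out_dir: Path, *, matrix: str, bins: str,
              tads_bed: str, **_) -> dict:
    p = cfg["tads"]
    hp = cfg["hic_stats"]
    m = _load_matrix(cfg, matrix, bins)
    balanced = hic.ice_balance(m, tol=hp["balance_tol"])
    iv = read_bed(tads_bed)
    ts = tads.TadSet(intervals=iv[["start", "end"]].to_numpy(),
                     bin_size=m.bin_size)
    grid, n_used = tads.aggregate_tads(balanced, ts, min_size=p["min_size"],
                                       out_pixels=p["out_pixels"],
                                       flank_fraction=p["flank_fraction"])
    np.savetxt(out_dir / "ata_grid.tsv", grid, delimiter="\t", fmt="%.8g")
    _write_json({"n_tads_aggregated": n_used}, out_dir / "ata.json")
    _log_params("ata", p | {"matrix": str(matrix)}, out_dir)
    return {"grid": out_dir / "ata_grid.tsv"}


def stage_rg(cfg: AnalysisConfig, out_dir: Path, *, image: str,
             mask: str | None = None, **_) -> dict:
    from . import geometry
    import tifffile

    p = cfg["rg"]
    stack = tifffile.imread(image).astype(float)
    binary = (tifffile.imread(mask) > 0) if mask else stack > 0
    clouds = geometry.label_components(binary, connectivity=p["connectivity"],
                                       intensity=stack)
    rows = []
    for cloud in clouds:
        res = geometry.radius_of_gyration(cloud,
                                          voxel_size=np.asarray(
                                              p["voxel_size"]))
        rows.append({"label": cloud.label, "rg_um": res.rg_um,
                     "n_voxels": res.n_voxels,
                     "center_z": res.center_um[0],
                     "center_y": res.center_um[1],
                     "center_x": res.center_um[2]})
    pd.DataFrame(rows).to_csv(out_dir / "rg.csv", index=False)
    _log_params("rg", p | {"image": str(image)}, out_dir)
    return {"rg": out_dir / "rg.csv"}


# ---------------------------------------------------------------------------
# end-to-end preset comparison


def compare_presets(seed: int = 0, n_bins: int = 400, bin_size: int = 100_000,
                    depth: float = 2_000_000, tad_size: int = 10,
                    block_size: int = 40) -> dict:
    """Paired control vs cohesin-overloaded synthetic maps, all contrasts.

    Simulates the two presets with paired seeds and recomputes every
    contact-map contrast: P(s) short/long-range change and crossing,
    mixing ratio, saddle corner enrichment, TAD-corner contacts, TAD
    score, and TAD count/length. Returns a flat dict of measured values
    plus booleans for each expected direction.
    """
    kwargs = dict(n_bins=n_bins, bin_size=bin_size, depth=depth,
                  tad_size=tad_size, block_size=block_size)
    ctrl_params = control_preset(seed=seed, **kwargs)
    oe_params = oe_preset(seed=seed + 10_000, **kwargs)
    m_ctrl, truth = simulate_contact_map(ctrl_params)
    m_oe, _ = simulate_contact_map(oe_params)

    out: dict = {}
    # the generator has no technical coverage dropout, so MAD-based
    # coverage masking would only discard informative structured bins
    b_ctrl = hic.ice_balance(m_ctrl, min_coverage_mad=0)
    b_oe = hic.ice_balance(m_oe, min_coverage_mad=0)

    # P(s): short-range up, long-range down, one crossing. "Short range"
    # is the TAD scale of the generator (up to 2 TAD sizes, where corner
    # peaks and adjacent-TAD mixing act); "long range" is beyond 4 TAD
    # sizes, where only the decay-exponent contrast remains.
    ps_ctrl = hic.contact_probability(b_ctrl)
    ps_oe = hic.contact_probability(b_oe)
    k = min(len(ps_ctrl.probabilities), len(ps_oe.probabilities))
    pc, po = ps_ctrl.probabilities[:k], ps_oe.probabilities[:k]
    centers = ps_ctrl.centers_bp[:k]
    pairs = np.minimum(ps_ctrl.pair_counts[:k], ps_oe.pair_counts[:k])
    diff = po - pc
    tad_bp = tad_size * bin_size
    short = centers <= 2 * tad_bp
    longr = (centers > 4 * tad_bp) & (pairs >= 100)
    out["ps_short_range_diff"] = float(np.mean(diff[short]))
    out["ps_long_range_diff"] = float(np.average(diff[longr],
                                                 weights=pairs[longr]))
    out["ps_short_range_up"] = bool(out["ps_short_range_diff"] > 0)
    out["ps_long_range_down"] = bool(out["ps_long_range_diff"] < 0)
    # crossing count on relative differences above a 5% noise floor,
    # well-sampled distance bins only
    rel = diff / (0.5 * (pc + po))
    sig = (np.abs(rel) >= 0.05) & (pairs >= 100)
    sign = np.sign(diff[sig])
    crossings = int(np.sum(sign[1:] != sign[:-1]))
    out["ps_single_crossing"] = bool(
        crossings == 1 and sign[0] > 0 and sign[-1] < 0)

    # mixing ratio AB/(AA+BB): up in the overloaded condition
    track = truth["labels"].astype(float)
    prof_ctrl = comp.compute_pc1(b_ctrl, track)
    prof_oe = comp.compute_pc1(b_oe, track)
    out["mixing_ratio_control"] = comp.mixing_ratio(b_ctrl, prof_ctrl)
    out["mixing_ratio_oe"] = comp.mixing_ratio(b_oe, prof_oe)
    out["mixing_ratio_up"] = bool(
        out["mixing_ratio_oe"] > out["mixing_ratio_control"])

    # saddle corner enrichment: down
    oe_ctrl_mat = hic.observed_over_expected(b_ctrl)
    oe_oe_mat = hic.observed_over_expected(b_oe)
    sad_ctrl = comp.saddle(oe_ctrl_mat, prof_ctrl)
    sad_oe = comp.saddle(oe_oe_mat, prof_oe)
    corner = lambda g: float((g[0, 0] + g[-1, -1]) / 2)  # noqa: E731
    out["saddle_corner_control"] = corner(sad_ctrl)
    out["saddle_corner_oe"] = corner(sad_oe)
    out["saddle_corner_down"] = bool(
        out["saddle_corner_oe"] < out["saddle_corner_control"])

    # corner contacts: differential positive at TAD corners
    n_ctrl = hic.normalize_total(m_ctrl, 1e8)
    n_oe = hic.normalize_total(m_oe, 1e8)
    dm = hic.differential_matrix(n_oe, n_ctrl)
    w = ctrl_params.corner_width
    corner_vals = []
    for s, t in truth["tads"]:
        if t - s > 2 * w:
            corner_vals.append(dm[s:s + w, t - w:t])
    corner_mean = float(np.nanmean(np.concatenate(
        [c.ravel() for c in corner_vals])))
    out["corner_diff_mean"] = corner_mean
    out["corner_contacts_up"] = bool(corner_mean > 0)

    # TAD calling and TAD score
    window = 5 * bin_size
    results = {}
    for name, bal in (("control", b_ctrl), ("oe", b_oe)):
        profile = tads.insulation_score(bal, window=window)
        profile = tads.call_boundaries(profile, delta_window=2 * bin_size,
                                       min_strength=0.1)
        ts = tads.tads_from_boundaries(profile.boundaries, bal.bins)
        stats = tads.tad_length_stats(ts)
        scores = tads.tad_score(bal, ts)["score"].dropna()
        results[name] = (stats, float(scores.median()))
    out["n_tads_control"] = results["control"][0]["n_tads"]
    out["n_tads_oe"] = results["oe"][0]["n_tads"]
    out["median_tad_length_control"] = results["control"][0]["median_length"]
    out["median_tad_length_oe"] = results["oe"][0]["median_length"]
    out["tad_count_unchanged"] = bool(
        out["n_tads_control"] == out["n_tads_oe"])
    out["tad_length_unchanged"] = bool(
        results["control"][0]["median_length"]
        == results["oe"][0]["median_length"])
    out["tad_score_control"] = results["control"][1]
    out["tad_score_oe"] = results["oe"][1]
    out["tad_score_down"] = bool(
        out["tad_score_oe"] < out["tad_score_control"])

    out["all_directions_reproduced"] = all(
        out[k] for k in ("ps_short_range_up", "ps_long_range_down",
                         "mixing_ratio_up", "saddle_corner_down",
                         "corner_contacts_up", "tad_score_down",
                         "tad_count_unchanged", "tad_length_unchanged"))
    return out


def stage_demo(cfg: AnalysisConfig, out_dir: Path, **_) -> dict:
    out = compare_presets(seed=cfg["global"]["seed"])
    _write_json(out, out_dir / "demo_contrasts.json")
    _log_params("demo", {"seed": cfg["global"]["seed"]}, out_dir)
    return {"report": out_dir / "demo_contrasts.json"}


STAGES = {
    "simulate-hic": stage_simulate_hic,
    "simulate-image": stage_simulate_image,
    "simulate-frap": stage_simulate_frap,
    "heterogeneity": stage_heterogeneity,
    "beads": stage_beads,
    "coloc": stage_coloc,
    "clusters": stage_clusters,
    "frap-fit": stage_frap_fit,
    "ifrap": stage_ifrap,
    "hic-stats": stage_hic_stats,
    "compartments": stage_compartments,
    "tads": stage_tads,
    "ata": stage_ata,
    "rg": stage_rg,
    "demo": stage_demo,
}


def run_pipeline(cfg: AnalysisConfig, stage: str, out_dir: str | Path | None
                 = None, **inputs) -> dict:
    """Run one registered stage; returns the paths it wrote."""
    if stage not in STAGES:
        raise UsageError(f"unknown stage {stage!r}; available: "
                         + ", ".join(sorted(STAGES)))
    out = Path(out_dir if out_dir is not None else cfg["global"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return STAGES[stage](cfg, out, **inputs)
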