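"""End-to-end demo pipeline with provenance tracking.

``run_demo`` executes the full analysis chain on a synthetic cell:

phantom -> {confocal, STED, hologram, SAXS scan}
        -> {CTF + RAAR phase retrieval, dark field, PCA anisotropy}
        -> {PSD resolution estimates, filament tracing}
        -> {registration, filament-vs-SAXS orientation agreement}

Every stage receives its own seed derived deterministically from the
master seed, so single stages can be re-run reproducibly.  All artifacts
are written to the output directory together with a manifest naming the
configuration hash, all seeds, and the SHA-256 of every file.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlate, filaments, holography, io, resolution, saxs
from . import phantom as ph
from .config import RunConfig
from .geometry import OpticalGeometry

STAGES = ("phantom", "fluorescence", "hologram", "scan", "registration")


def derive_seeds(master_seed: int, stages: tuple[str, ...] = STAGES) -> dict[str, int]:
    """Per-stage seeds (all < 2^31) derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(stages))
    return {name: int(s % (2**31)) for name, s in zip(stages, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_demo(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; returns the report dict (also written as
    ``manifest.json`` in ``outdir``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = derive_seeds(config.seed)
    report: dict = {"config_digest": config.digest(), "seeds": seeds}

    # ---- phantom ---------------------------------------------------------
    pc = config.phantom
    cell = ph.make_cell_phantom(
        n_filaments=pc.n_filaments,
        orientation_spread=pc.orientation_spread,
        label_fraction=pc.label_fraction,
        shape=pc.shape,
        pixel_size=pc.pixel_size,
        seed=seeds["phantom"],
        main_axis=pc.main_axis,
        filament_width=pc.filament_width,
        filament_amp=pc.filament_amp,
        envelope_amp=pc.envelope_amp,
        nucleus_scale=pc.nucleus_scale,
        nucleus_texture_amp=pc.nucleus_texture_amp,
        nucleus_texture_nm=pc.nucleus_texture_nm,
        phase_scale=pc.phase_scale,
    )
    io.save_phantom(outdir / "phantom.tif", cell)

    # ---- fluorescence ----------------------------------------------------
    fc = config.fluorescence
    d_min = resolution.diffraction_limit(fc.wavelength_fl, fc.na)
    confocal = ph.render_fluorescence(
        cell, d_min, fc.photon_budget, "confocal", seeds["fluorescence"]
    )
    sted = ph.render_fluorescence(
        cell, d_min / fc.sted_gain, fc.photon_budget, "sted",
        seeds["fluorescence"] + 1,
    )
    io.save_image(outdir / "confocal.tif", confocal.counts,
                  {"pixel_size_nm": confocal.pixel_size, "psf_fwhm_nm": d_min})
    io.save_image(outdir / "sted.tif", sted.counts,
                  {"pixel_size_nm": sted.pixel_size, "psf_fwhm_nm": d_min / fc.sted_gain})
    report["diffraction_limit_nm"] = d_min

    # ---- holography ------------------------------------------------------
    gc = config.geometry
    hc = config.holography
    geom = OpticalGeometry(
        photon_energy=gc.photon_energy, z1=gc.z1, z2=gc.z2, pixel_size=gc.pixel_size
    )
    holo = ph.simulate_hologram(
        cell, geom, photon_budget=hc.photon_budget,
        offset_px=hc.offset_px, seed=seeds["hologram"],
    )
    io.save_hologram(outdir / "hologram.tif", holo)
    phase_ctf = holography.ctf_phase_retrieval(
        holo, hc.alpha_low, hc.alpha_high, zero_border=hc.zero_border
    )
    support = holography.estimate_support(
        phase_ctf, hc.support_smoothing_fwhm, hc.support_threshold, hc.support_dilation
    )
    raar = holography.raar_reconstruct(
        holo, support, beta=hc.beta, n_iter=hc.n_iter, init=phase_ctf
    )
    io.save_phase_map(outdir / "phase_ctf.tif", phase_ctf)
    io.save_phase_map(outdir / "phase_raar.tif", raar.phase_map)
    io.save_image(outdir / "support.tif", support.astype(np.float32))
    pd.DataFrame(
        {"iteration": np.arange(1, len(raar.residuals) + 1),
         "residual": raar.residuals}
    ).to_csv(outdir / "raar_residuals.csv", index=False)
    report["geometry"] = geom.to_dict()
    report["raar_final_residual"] = float(raar.residuals[-1])

    # ---- scanning SAXS ---------------------------------------------------
    sc = config.scan
    beam = ph.BeamProfile(sc.fwhm_y, sc.fwhm_z, sc.flux, sc.exposure)
    grid = saxs.ScanGrid(shape=sc.shape, step_um=sc.step_um, origin_um=sc.origin_um)
    stack = ph.simulate_scan_saxs(
        cell, beam, grid,
        background_rate=sc.background_rate, det_size=sc.det_size,
        beamstop_radius=sc.beamstop_radius, gap_width=sc.gap_width,
        wavelength_nm=geom.wavelength, seed=seeds["scan"],
    )
    io.save_scan_stack(outdir / "scanstack.h5", stack)
    df = saxs.darkfield(stack)
    valid = saxs.threshold_map(df, config.saxs.darkfield_threshold)
    aniso = saxs.anisotropy_map(
        stack, threshold=config.saxs.darkfield_threshold, q_range=config.saxs.q_range
    )
    io.save_image(outdir / "darkfield.tif", df.values, {"units": "photons",
                  "exposure_s": df.exposure, "step_um": df.step_um})
    pd.DataFrame(df.rates).to_csv(outdir / "darkfield_rates.csv", index=False)
    for name, arr in [("omega", aniso.omega), ("theta_real", aniso.theta_real)]:
        pd.DataFrame(arr).to_csv(outdir / f"aniso_{name}.csv", index=False)
    report["darkfield_valid_points"] = int(valid.sum())
    report["darkfield_max_rate_ph_s"] = float(df.rates.max())

    # azimuthal profile of the frame with the strongest dark field
    iz, iy = np.unravel_index(np.argmax(df.values), df.values.shape)
    qmap = saxs.q_map(stack.calibration, stack.counts.shape[2:])
    qc, prof, _ = saxs.azimuthal_average(
        stack.counts[iz, iy], stack.mask, qmap, n_bins=config.saxs.n_radial_bins
    )
    pd.DataFrame({"q_nm_inv": qc, "intensity": prof}).to_csv(
        outdir / "radial_profile_nucleus.csv", index=False
    )

    # ---- resolution (PSD cross-overs) -----------------------------------
    fits = {}
    curves = {
        "confocal": resolution.power_spectral_density(
            confocal.counts, confocal.pixel_size, config.psd.window, modality="confocal"
        ),
        "sted": resolution.power_spectral_density(
            sted.counts, sted.pixel_size, config.psd.window, modality="sted"
        ),
        "holography": resolution.power_spectral_density(
            raar.phase_map.phase, raar.phase_map.pixel_size, config.psd.window,
            modality="holography",
        ),
    }
    for name, curve in curves.items():
        pd.DataFrame({"q_nm_inv": curve.q, "psd": curve.psd}).to_csv(
            outdir / f"psd_{name}.csv", index=False
        )
        if name == "holography":
            # the phase map lives on a coarser grid: its Nyquist q is lower
            qmax = curve.q[-1]
            ranges = ((0.05 * qmax, 0.3 * qmax), (0.75 * qmax, qmax))
        else:
            ranges = (config.psd.signal_range, config.psd.noise_range)
        try:
            fit = resolution.fit_power_law(curve, *ranges)
            fits[name] = {
                "a": fit.a, "b": fit.b, "bgr": fit.bgr,
                "q_i_nm_inv": fit.q_i, "d_cr_nm": fit.d_cr, "valid": fit.valid,
            }
        except ValueError as exc:
            fits[name] = {"error": str(exc)}
    io.save_json(outdir / "psd_fits.json", fits)
    report["psd_fits"] = fits

    # ---- filament tracing ------------------------------------------------
    tc = config.tracer
    fs = filaments.trace_filaments(
        sted.counts, smoothing=tc.smoothing, n_orientations=tc.n_orientations,
        line_length=tc.line_length, threshold=tc.threshold,
        min_segment=tc.min_segment,
    )
    fs.pixel_size = sted.pixel_size
    fs.source = "sted"
    fs.to_dataframe().to_csv(outdir / "filaments_sted.csv", index=False)
    edges, hist = filaments.orientation_histogram(fs)
    pd.DataFrame({"bin_left_deg": edges[:-1], "length_px": hist}).to_csv(
        outdir / "orientation_histogram.csv", index=False
    )
    report["n_filaments_traced"] = len(fs)

    # ---- registration ----------------------------------------------------
    # bring STED and the reconstructed phase onto the phase-map grid;
    # the configured stage offset between modalities must be recovered
    p_eff = raar.phase_map.pixel_size
    sted_coarse = correlate.rebin(
        sted.counts.astype(float), sted.pixel_size, p_eff, "sum"
    )
    canvas = np.zeros_like(raar.phase_map.phase)
    r0 = (canvas.shape[0] - sted_coarse.shape[0]) // 2
    c0 = (canvas.shape[1] - sted_coarse.shape[1]) // 2
    canvas[r0 : r0 + sted_coarse.shape[0], c0 : c0 + sted_coarse.shape[1]] = sted_coarse
    reg = correlate.register_translation(
        -raar.phase_map.phase, canvas, pixel_size=p_eff,
        upsampling=config.registration.upsampling,
    )
    report["registration"] = {
        "shift_y_nm": reg.shift_y, "shift_z_nm": reg.shift_z, "score": reg.score,
        "expected_shift_px": list(config.holography.offset_px),
    }

    # ---- orientation agreement (STED filaments vs SAXS anisotropy) ------
    table, summary = correlate.orientation_agreement(
        fs, aniso, grid, pixel_size_nm=sted.pixel_size
    )
    table.to_csv(outdir / "orientation_agreement.csv", index=False)
    report["orientation_agreement"] = summary

    # ---- ground-truth validation ----------------------------------------
    truth_cells = ph.single_filament_cells(cell, grid)
    errs = [
        filaments.circular_distance(aniso.theta_real[c], th)
        for c, th in truth_cells.items()
        if aniso.valid[c] and not np.isnan(aniso.theta_real[c])
    ]
    report["saxs_theta_vs_truth"] = {
        "n_points": len(errs),
        "median_circular_error_deg": float(np.median(errs)) if errs else float("nan"),
    }

    report["runtime_s"] = time.time() - t0
    config.save(outdir / "config.yaml")
    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    report["artifacts"] = {name: _sha256(outdir / name) for name in files}
    io.save_json(outdir / "manifest.json", report)
    return report
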