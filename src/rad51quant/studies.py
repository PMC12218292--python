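"""Validation studies: recovery and calibration of the pipeline on known truth.

Each study generates synthetic data with planted ground truth, runs the
corresponding pipeline stage end to end, and reports summary metrics.  They
back both the acceptance checks and any re-calibration after a parameter
change.  All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import PipelineConfig
from .nmr import call_interaction_region, intensity_ratio
from .pipeline import analyze_cell
from .stats import MODELS, all_pairs, compare_all, fit_pair_model
from .synthetic import (AcquisitionParams, StrainDesign, default_strain_designs,
                        render_cell, simulate_cell_records, simulate_experiment,
                        simulate_nmr_titration, synthetic_rad52_cterm_sequence)

__all__ = [
    "category_recovery_study",
    "length_recovery_study",
    "intensity_recovery_study",
    "type_i_error_study",
    "fdr_control_study",
    "nmr_region_study",
]

_ARCHETYPE_TO_CATEGORY = {"simple": "Simple", "complex": "Complex",
                          "foci_only": "Foci", "nothing": "Nothing"}


def _subseed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def category_recovery_study(n_cells: int = 125, n_batches: int = 3,
                            seed: int = 0) -> dict:
    """Per-cell category accuracy on a four-strain synthetic experiment."""
    config = PipelineConfig()
    designs = default_strain_designs(n_batches)
    cells, truth = simulate_experiment(designs, n_cells=n_cells, n_batches=n_batches,
                                       acq=config.acquisition, seed=seed)
    correct = 0
    for (stack, meta), archetype in zip(cells, truth["archetype"]):
        result = analyze_cell(stack, config, cell_id=meta["cell_id"])
        correct += result["category"] == _ARCHETYPE_TO_CATEGORY[archetype]
    return {"accuracy_pct": 100.0 * correct / len(cells), "n": len(cells)}


def length_recovery_study(lengths=(5, 8, 12, 16, 20, 25, 30),
                          seeds_per_length: int = 4, seed: int = 0) -> dict:
    """Relative length error for noise-free planted straight filaments."""
    acq = AcquisitionParams(poisson=False, read_noise_sd=0.0)
    config = PipelineConfig()
    errors = []
    for length in lengths:
        design = StrainDesign(
            name="probe", category_probs={"simple": 1.0},
            filament_length_px=(float(length), 1e-9, length - 0.01, length + 0.01),
            filament_photons=(50_000.0, 1e-9), max_bow_frac=0.0)
        for i in range(seeds_per_length):
            stack, truth = render_cell(design, "simple", acq,
                                       rng_seed=_subseed(seed, 1000 * length + i))
            result = analyze_cell(stack, config)
            true_len = truth.filaments[0].length_px
            est = result["filament_length_px"]
            errors.append(abs(est - true_len) / true_len if np.isfinite(est) else 1.0)
    errors = np.asarray(errors)
    return {"max_rel_error": float(errors.max()),
            "mean_rel_error": float(errors.mean()), "n": int(errors.size)}


def intensity_recovery_study(n_seeds: int = 100, seed: int = 0) -> dict:
    """Bias of background-subtracted intensities vs planted photons.

    One filament (50k photons) and one focus (8k photons) cell per seed,
    under the default noisy acquisition; reports the mean measured / planted
    ratio and the bias in units of the standard error of the mean.
    """
    acq = AcquisitionParams()
    config = PipelineConfig()
    fil_design = StrainDesign(name="probe", category_probs={"simple": 1.0},
                              filament_photons=(50_000.0, 1e-9))
    foc_design = StrainDesign(name="probe", category_probs={"foci_only": 1.0},
                              foci_count_mean=0.0, focus_photons=(8_000.0, 1e-9))
    out = {}
    for label, design, archetype, m_key, t_attr in [
            ("filament", fil_design, "simple", "filament_intensity", "filaments"),
            ("focus", foc_design, "foci_only", "spot_intensity", "foci")]:
        measured, planted = [], []
        for i in range(n_seeds):
            stack, truth = render_cell(design, archetype, acq,
                                       rng_seed=_subseed(seed, 77_000 + i))
            result = analyze_cell(stack, config)
            if np.isfinite(result.get(m_key, np.nan)):
                measured.append(result[m_key])
                planted.append(getattr(truth, t_attr)[0].planted_photons)
        measured, planted = np.asarray(measured), np.asarray(planted)
        se = measured.std(ddof=1) / np.sqrt(len(measured))
        out[f"{label}_recovery_ratio"] = float(measured.mean() / planted.mean())
        out[f"{label}_bias_in_se"] = float((measured.mean() - planted.mean()) / se)
        out[f"{label}_n"] = int(len(measured))
    return out


def _null_pair(n_strains: int = 2) -> list:
    base = default_strain_designs(3)[0]
    return [dataclasses.replace(base, name=f"S{i}") for i in range(n_strains)]


def type_i_error_study(reps: int = 1000, n_cells: int = 200, seed: int = 0) -> dict:
    """Wald-test rejection rate at alpha = 0.05 under the null.

    Two strains drawn from the same design; one fraction per model.
    """
    designs = _null_pair(2)
    rejections = {m: 0 for m in ("M1", "M2", "M3")}
    totals = {m: 0 for m in ("M1", "M2", "M3")}
    for r in range(reps):
        records = simulate_cell_records(designs, n_cells=n_cells, n_batches=3,
                                        seed=_subseed(seed, r))
        for model_id in rejections:
            for res in fit_pair_model(records, ("S0", "S1"), MODELS[model_id]):
                if np.isfinite(res.p):
                    totals[model_id] += 1
                    rejections[model_id] += res.p < 0.05
    return {f"type_i_{m}": rejections[m] / max(totals[m], 1) for m in rejections} | \
        {"reps": reps}


def fdr_control_study(reps: int = 500, n_cells: int = 200, n_strains: int = 4,
                      seed: int = 0) -> dict:
    """Mean false-discovery proportion at q < 0.05, all hypotheses null."""
    designs = _null_pair(n_strains)
    pairs = all_pairs([d.name for d in designs])
    fdps = []
    for r in range(reps):
        records = simulate_cell_records(designs, n_cells=n_cells, n_batches=3,
                                        seed=_subseed(seed, 500_000 + r))
        tests = compare_all(records, pairs)
        fdps.append(1.0 if (tests["q"] < 0.05).any() else 0.0)
    return {"mean_fdp": float(np.mean(fdps)), "reps": reps,
            "n_hypotheses": len(pairs) * 4}


def nmr_region_study(reps: int = 200, noise_cv: float = 0.10, seed: int = 0) -> dict:
    """Recovery of the planted 310-395 attenuated segment.

    Zero noise must recover the exact boundaries; under multiplicative
    noise the boundaries must land within 2 residues in the stated fraction
    of replicates.
    """
    sequence = synthetic_rad52_cterm_sequence()
    free, bound = simulate_nmr_titration(sequence, region=(310, 395), attenuation=0.2,
                                         noise_cv=0.0, seed=_subseed(seed, 1),
                                         start_residue=206)
    zero_calls = call_interaction_region(intensity_ratio(bound, free))
    start = zero_calls[0].start_residue if zero_calls else -1
    end = zero_calls[0].end_residue if zero_calls else -1
    recovered = 0
    for r in range(reps):
        free, bound = simulate_nmr_titration(sequence, region=(310, 395),
                                             attenuation=0.2, noise_cv=noise_cv,
                                             seed=_subseed(seed, 900_000 + r),
                                             start_residue=206)
        calls = call_interaction_region(intensity_ratio(bound, free))
        if (len(calls) == 1 and abs(calls[0].start_residue - 310) <= 2
                and abs(calls[0].end_residue - 395) <= 2):
            recovered += 1
    return {"zero_noise_start": int(start), "zero_noise_end": int(end),
            "n_zero_noise_calls": len(zero_calls),
            "recovery_pct": 100.0 * recovered / reps, "reps": reps}
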