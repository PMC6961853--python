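"""Canonical synthetic-study conditions and end-to-end metric runners.

These are the reference experiments the package documents and tests:

- a heterogeneous-loading cohort (12 participants x 60 calls) where which
  speech channels track clinical state is individual — the setting in
  which personalized models should clearly beat population models;
- a shared-loading cohort (20 x 48) where one feature-state pattern is
  common to everyone — the setting in which leave-one-subject-out
  population models are learnable;
- a diagnosis cohort at a realistic clinic scale (47 participants) whose
  labels are random by construction, for the null classification check.

Each runner simulates, extracts the 210-feature battery with the bundled
demo lexicons, runs the requested analysis, and returns plain floats.
"""

from __future__ import annotations

import numpy as np

from speechstate.feature_assembly import CallFeatureRow, extract_cohort_features, rows_to_frame
from speechstate.state_models import (
    ClinicalStateTracker,
    DiagnosisClassifier,
    ModelConfig,
)
from speechstate.state_statistics import (
    half_split_stability,
    individual_profiles,
    population_feature_correlations,
)
from speechstate.synthetic_cohort import (
    SimulationParams,
    demo_lexicons,
    moving_average_improvement_fraction,
    simulate_cohort,
)


def heterogeneous_study(seed: int = 0) -> SimulationParams:
    """12 participants x 60 calls, individual channel loadings."""
    return SimulationParams(
        n_participants=12, calls_per_participant=60, loading_mode="heterogeneous",
        seed=seed,
    )


def shared_study(seed: int = 0) -> SimulationParams:
    """20 participants x 48 calls, one common loading pattern."""
    return SimulationParams(
        n_participants=20, calls_per_participant=48, loading_mode="shared", seed=seed
    )


def diagnosis_study(seed: int = 0) -> SimulationParams:
    """47 participants x 20 calls for the null diagnosis classification."""
    return SimulationParams(
        n_participants=47, calls_per_participant=20, loading_mode="heterogeneous",
        seed=seed,
    )


def simulate_and_extract(
    params: SimulationParams,
) -> tuple[list[CallFeatureRow], dict[str, str]]:
    """Simulate a cohort and extract every call's 210 features in memory."""
    cohort = simulate_cohort(params)
    norm, cat = demo_lexicons()
    rows, _ = extract_cohort_features(cohort, norm, cat)
    return rows, cohort.diagnoses


def tracking_metrics(
    rows: list[CallFeatureRow],
    seed: int = 0,
    modes: tuple[str, ...] = (
        "population_concurrent",
        "population_forecast",
        "personalized_concurrent",
        "personalized_forecast",
    ),
) -> dict[str, float]:
    """Windowed nested-CV tracking: mean per-participant rho and p per mode."""
    tracker = ClinicalStateTracker(rows, ModelConfig(seed=seed))
    results = tracker.fit(modes=modes)
    out: dict[str, float] = {}
    for mode, ev in results.evaluations.items():
        out[f"{mode}_mean_rho"] = ev.mean_rho
        out[f"{mode}_p_vs_baseline"] = ev.p_vs_baseline
    return out


def correlation_metrics(
    rows: list[CallFeatureRow],
    min_calls: int = 35,
    min_half: int = 10,
) -> dict[str, float]:
    """Population correlation strength, profile similarity, stability."""
    frame = rows_to_frame(rows)
    names = [c for c in frame.columns if c.startswith("q")]
    report = population_feature_correlations(frame, feature_names=names)
    profiles, similarity = individual_profiles(
        frame, feature_names=names, min_calls=min_calls
    )
    stable = []
    for _, sub in frame.groupby("participant_id"):
        if len(sub) >= 2 * min_half:
            rep = half_split_stability(sub, feature_names=names, min_half=min_half)
            stable.append(rep.stable_fraction)
    return {
        "mean_abs_rho": report.mean_abs_rho,
        "mean_pairwise_profile_similarity": similarity,
        "n_profiled_participants": float(len(profiles)),
        "mean_stable_fraction": float(np.mean(stable)) if stable else float("nan"),
    }


def diagnosis_metrics(
    rows: list[CallFeatureRow],
    labels: dict[str, str],
    seed: int = 0,
    n_permutations: int = 200,
) -> dict[str, float]:
    """Null diagnosis classification: UAR and its permutation p-value."""
    clf = DiagnosisClassifier.from_feature_table(
        rows_to_frame(rows), labels, ModelConfig(seed=seed)
    )
    res = clf.fit(n_permutations=n_permutations)
    return {"uar": res.uar, "permutation_p": res.permutation_p}


def moving_average_metrics(seed: int = 0, n_replicates: int = 100) -> dict[str, float]:
    """Fraction of replicates where 8-window averaging raises |rho|."""
    frac = moving_average_improvement_fraction(
        n_replicates=n_replicates, seed=seed + 12345
    )
    return {"improvement_fraction": frac}
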