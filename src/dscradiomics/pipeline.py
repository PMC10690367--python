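"""End-to-end orchestration: phantoms -> maps -> features -> CV report.

Thin glue over the computational modules, shared by the CLI, the tests
and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluate, features, maps, synth

__all__ = [
    "phantom_maps",
    "cohort_feature_table",
    "run_cohort_analysis",
]


def phantom_maps(
    phantom: synth.Phantom,
    *,
    gamma: bool = True,
    unidirectional: bool = True,
    bidirectional: bool = True,
) -> maps.ParametricMapSet:
    """Compute all requested parametric maps for one phantom, using the
    phantom's own AIF (already in concentration units)."""
    spec = phantom.spec
    aif = synth.make_aif(spec.aif_params, phantom.time_grid)
    return maps.compute_all_maps(
        phantom.series,
        aif,
        phantom.time_grid,
        phantom.masks["brain"],
        phantom.masks["tumor"],
        spec.te,
        spec.n_baseline,
        gamma=gamma,
        unidirectional=unidirectional,
        bidirectional=bidirectional,
    )


def cohort_feature_table(
    phantoms: list[synth.Phantom],
    config: features.FeatureConfig | None = None,
    *,
    map_names: list[str] | None = None,
    gamma: bool = True,
    unidirectional: bool = True,
    bidirectional: bool = True,
) -> pd.DataFrame:
    """Radiomic feature table over a phantom cohort (rows = phantoms)."""
    subjects = []
    labels = []
    for ph in phantoms:
        mset = phantom_maps(
            ph, gamma=gamma, unidirectional=unidirectional,
            bidirectional=bidirectional,
        )
        selected = {
            k: v for k, v in mset.maps.items()
            if map_names is None or k in map_names
        }
        roi = ph.masks["tumor"] & mset.validity
        if not roi.any():
            roi = ph.masks["tumor"]
        subjects.append((selected, roi))
        labels.append(ph.label)
    return features.extract_cohort_table(subjects, labels, config)


def run_cohort_analysis(
    feature_table: pd.DataFrame,
    *,
    k: int = 5,
    seed: int = 0,
    classifier_kwargs: dict | None = None,
) -> dict[str, evaluate.CVReport]:
    """Cross-validate one classifier per parametric map and return the
    per-map reports."""
    return evaluate.cross_validate_all_maps(
        feature_table, k=k, seed=seed, classifier_kwargs=classifier_kwargs
    )


def best_map_by_accuracy(reports: dict[str, evaluate.CVReport]) -> str:
    accs = {name: float(r.mean["accuracy"]) for name, r in reports.items()}
    return max(accs, key=lambda name: (np.nan_to_num(accs[name]), name))
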