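"""End-to-end synthetic experiments tying the pipeline together.

The parity experiment mirrors the comparison of automated versus expert
segmentation: one signature is trained on reference-mask features, then the
same cases are re-scored from boundary-perturbed masks and the paired AUCs
are compared with the DeLong test.  A sub-voxel perturbation should leave the
signature's discrimination statistically unchanged; a gross (several-mm)
perturbation should degrade it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_features, feature_columns
from .model import delong_test, roc_auc, score_table, youden_cutoff
from .phantom import PhantomParams, make_cohort, simulate_observer_mask
from .selection import run_cascade
from .utils import derive_seed

#: reduced phantom for cohort-scale runs (same anatomy, smaller field of view)
COHORT_PARAMS = PhantomParams(
    grid_shape=(72, 72, 56),
    body_semi_axes_mm=(12.0, 9.0, 20.0),
    lesion_radius_mm=5.0,
)

#: feature settings for cohort-scale runs: native grid, no resampling
COHORT_FEATURES = FeatureConfig(resample_spacing_mm=None)


def _perturbed_table(cases, displacement_mm: float, seed: int, config: FeatureConfig) -> pd.DataFrame:
    rows = []
    for i, case in enumerate(cases):
        mask = simulate_observer_mask(
            case.truth_mask, displacement_mm, derive_seed(seed, "parity", i)
        )
        cid = f"{case.patient_id}:{case.vertebra_id}"
        fv = extract_features(case.volume, mask, config, case_id=cid, label=case.label)
        row = fv.values.copy()
        row["label"] = case.label
        row["patient_id"] = case.patient_id
        row.name = cid
        rows.append(row)
    return pd.DataFrame(rows)


def truth_table(cases, config: FeatureConfig = COHORT_FEATURES) -> pd.DataFrame:
    from .features import extract_table

    return extract_table(cases, config)


def train_signature(table: pd.DataFrame, seed: int, repeats=(), n_folds: int = 5):
    """Cascade + LASSO on a labelled feature table; Youden cutoff on the
    training scores."""
    feats = table[feature_columns(table)]
    labels = (table["label"] == "malignant").astype(int).to_numpy()
    spec, params, report = run_cascade(feats, labels, repeats, n_folds=n_folds, seed=seed)
    scores = score_table(spec, feats).to_numpy()
    cutoff, _ = youden_cutoff(scores, labels)
    return spec.with_cutoff(cutoff), report


def _split_by_patient(table: pd.DataFrame, seed: int):
    """Half/half patient-level split, stratified by class.

    Each patient owns vertebrae of a single class, so splitting every
    class's patient list in half keeps both classes represented on both
    sides.
    """
    rng = np.random.default_rng(seed)
    train_p: set[str] = set()
    for _, sub in table.groupby("label", sort=True):
        patients = sorted(sub["patient_id"].unique())
        rng.shuffle(patients)
        train_p.update(patients[: (len(patients) + 1) // 2])
    tr = table[table["patient_id"].isin(train_p)]
    te = table[~table["patient_id"].isin(train_p)]
    return tr, te


def parity_experiment(
    n_per_class: int = 30,
    seed: int = 1,
    small_mm: float = 0.5,
    large_mm: float = 3.0,
    params: PhantomParams = COHORT_PARAMS,
    config: FeatureConfig = COHORT_FEATURES,
    n_folds: int = 5,
) -> dict:
    """Held-out comparison of reference-mask and perturbed-mask radiomics.

    The cohort is split in half by patient; the signature is trained on the
    reference-mask features of the training half, and evaluation happens on
    the held-out half: its reference features, and its features re-extracted
    from perturbed masks, are scored by the same model and the paired AUCs
    compared with the DeLong test.
    """
    cases = make_cohort(
        n_per_class, n_per_class, params, seed=derive_seed(seed, "cohort"), n_observers=0
    )
    table = truth_table(cases, config)
    tr, te = _split_by_patient(table, derive_seed(seed, "split"))
    spec, report = train_signature(tr, seed=derive_seed(seed, "train"), n_folds=n_folds)

    eval_cases = [
        c for c in cases if f"{c.patient_id}:{c.vertebra_id}" in set(te.index)
    ]
    labels = (te["label"] == "malignant").astype(int).to_numpy()
    s_ref = score_table(spec, te[feature_columns(te)]).to_numpy()

    out = {
        "n_cases": len(cases),
        "n_train": len(tr),
        "n_eval": len(te),
        "n_signature_features": len(spec.feature_names),
        "auc_reference": roc_auc(s_ref, labels)["auc"],
    }
    for name, disp in (("small", small_mm), ("large", large_mm)):
        tab = _perturbed_table(eval_cases, disp, derive_seed(seed, name), config)
        tab = tab.loc[te.index]
        s_pert = score_table(spec, tab[feature_columns(tab)]).to_numpy()
        dl = delong_test(s_ref, s_pert, labels)
        out[f"auc_{name}"] = dl["auc_b"]
        out[f"delong_p_{name}"] = dl["p"]
        out[f"displacement_mm_{name}"] = disp
    return out


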