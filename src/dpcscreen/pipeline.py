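"""Two-step anti-fibrotic screen orchestration.

Step 1 (classifier gate): each compound's fields at the decision time
point (24 h) are classified into activation types 0-5; the per-compound
type is the majority vote (ties broken toward the higher, more fibrotic
type) and the gate passes types 0-3.

Step 2 (morphology-statistics gate): the compound's relative-count
readout must be a *hit* under the cumulative-distribution filter at the
primary screening concentration, and its morphology profile (restricted
to the correlated "common parameter" feature set) must fall inside the
control cluster — Mahalanobis membership in PCA space — at one or more
confirmation concentrations.

Final hits are the intersection of the two gates, computed only on
plates passing Z'/CV quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import qc as qc_mod
from .classifier import TrainedClassifier, classify, group_type
from .errors import MissingDataError
from .markers import control_membership, pca_profiles
from .morphometry import extract_features
from .phantoms import ScreenDataset, simulate_confirmation
from .segmentation import count_cells, segment_cells
from .timeseries import proliferation_curve

#: default morphology profile features for the step-2 gate (the shape
#: features that track activation state; replaceable by the data-driven
#: common-parameter selection from :mod:`dpcscreen.markers`)
DEFAULT_PROFILE_FEATURES: tuple[str, ...] = (
    "cell_area",
    "cell_roundness",
    "cell_length",
    "cell_width",
    "cell_aspect_ratio",
    "cell_eccentricity",
    "cell_equivalent_diameter",
)

CONFIRMATION_CONCS_UM: tuple[float, ...] = (20.0, 10.0, 5.0, 1.0)


@dataclass
class ScreenResult:
    """Per-compound decisions plus plate QC and the funnel summary."""

    table: pd.DataFrame
    plate_qc: list[qc_mod.PlateQc]
    funnel: dict
    well_readouts: pd.DataFrame

    def final_hits(self) -> list[str]:
        return sorted(self.table.index[self.table["final_hit"]])

    def evaluate(self, truth_labels: dict[str, str]) -> dict:
        """Sensitivity/precision of the final hit set vs planted truth."""
        hits = set(self.final_hits())
        inhibitors = {c for c, e in truth_labels.items() if e == "inhibitor"}
        tp = len(hits & inhibitors)
        sens = tp / len(inhibitors) if inhibitors else float("nan")
        prec = tp / len(hits) if hits else float("nan")
        return {
            "n_hits": len(hits),
            "n_inhibitors": len(inhibitors),
            "true_positives": tp,
            "sensitivity": sens,
            "precision": prec,
        }


def segmentation_params(render_scale: float) -> dict:
    """Segmentation parameters matched to the phantom render scale."""
    min_area = max(5, int(round(60 * render_scale**2)))
    return {
        "min_area": min_area,
        "smoothing_scale": max(0.6, 2.0 * render_scale),
    }


def compute_well_readouts(dataset: ScreenDataset) -> pd.DataFrame:
    """Segment every well's frames and form relative counts at 24 h."""
    params = segmentation_params(dataset.render_scale)
    source = dataset.readout_images or dataset.images
    rows = []
    for rec in dataset.wells:
        frames = source[rec.well_id]
        # counts are summed over fields at each time point
        per_time: dict[float, int] = {}
        for f in frames:
            c = count_cells(segment_cells(f, "dpc", **params))
            per_time[f.time_h] = per_time.get(f.time_h, 0) + c
        times = sorted(per_time)
        counts = [per_time[t] for t in times]
        try:
            curve = proliferation_curve(counts, times, well_id=rec.well_id)
            rel = float(curve.relative_count[-1])
        except Exception:
            rel = float("nan")
        rows.append(
            {
                "well_id": rec.well_id,
                "plate_id": rec.plate_id,
                "role": rec.role,
                "compound_id": rec.compound_id,
                "count_0": counts[0],
                "count_final": counts[-1],
                "relative_count": rel,
            }
        )
    return pd.DataFrame(rows)


def run_plate_qc(
    readouts: pd.DataFrame, z_prime_min: float = 0.5, cv_max: float | None = None
) -> list[qc_mod.PlateQc]:
    out = []
    for plate_id, grp in readouts.groupby("plate_id"):
        ctrl = grp.loc[grp["role"] == "control", "relative_count"].dropna()
        model = grp.loc[grp["role"] == "model", "relative_count"].dropna()
        out.append(
            qc_mod.plate_qc(str(plate_id), ctrl.to_numpy(), model.to_numpy(),
                            z_prime_min=z_prime_min, cv_max=cv_max)
        )
    return out


def majority_type(types: list[int]) -> int:
    """Majority vote over per-field types; ties go to the higher type."""
    if not types:
        raise MissingDataError("no classified fields for this compound")
    vals, counts = np.unique(types, return_counts=True)
    best = counts.max()
    return int(vals[counts == best].max())


def step1_classifier_gate(types_by_compound: dict[str, list[int]]) -> pd.Series:
    """Pass compounds whose majority type at the decision time is 0-3."""
    out = {}
    for cid, types in types_by_compound.items():
        out[cid] = majority_type(types) <= 3
    return pd.Series(out, dtype=bool)


def compound_profiles(
    dataset: ScreenDataset,
    wells: list,
    images: dict,
    feature_names=DEFAULT_PROFILE_FEATURES,
    index_by: str = "well_id",
) -> pd.DataFrame:
    """Mean per-well morphology profile from the final frame of each well."""
    params = segmentation_params(dataset.render_scale)
    rows = {}
    for rec in wells:
        frame = images[rec.well_id][-1]
        mask = segment_cells(frame, "dpc", **params)
        feats = extract_features(frame, mask, "dpc", well_id=rec.well_id)
        if feats.empty:
            continue
        key = rec.well_id if index_by == "well_id" else getattr(rec, index_by)
        rows[key] = feats[list(feature_names)].mean()
    return pd.DataFrame(rows).T


def step2_morphology_gate(
    cumulative: pd.DataFrame,
    profiles_by_dose: dict[float, pd.DataFrame],
    control_profiles: pd.DataFrame,
    membership_quantile: float = 0.975,
    n_components: int = 2,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cumulative hit at the primary dose AND PCA control membership.

    ``profiles_by_dose`` maps each confirmation concentration to a
    compound x feature profile table; membership at any one
    concentration satisfies the PCA criterion.  Returns the pass flags
    and the per-dose membership table.
    """
    compounds = list(cumulative.index)
    membership = pd.DataFrame(False, index=compounds, columns=sorted(profiles_by_dose))
    for conc, prof in profiles_by_dose.items():
        if prof.empty:
            continue
        ctrl_ids = [f"CTRL::{w}" for w in control_profiles.index]
        all_prof = pd.concat(
            [control_profiles.set_axis(ctrl_ids), prof], axis=0
        )
        proj = pca_profiles(all_prof, n_components=n_components, control_conditions=ctrl_ids)
        member = control_membership(proj, ctrl_ids, quantile=membership_quantile)
        for cid in prof.index:
            if cid in membership.index:
                membership.loc[cid, conc] = bool(member.loc[cid])
    any_member = membership.any(axis=1)
    passed = (
        cumulative["hit"].reindex(compounds, fill_value=False).astype(bool) & any_member
    )
    return passed, membership


def final_hit_call(step1: pd.Series, step2: pd.Series) -> pd.Series:
    """Final hits: compounds passing both gates (logical AND)."""
    idx = step1.index.union(step2.index)
    return (
        step1.reindex(idx, fill_value=False).astype(bool)
        & step2.reindex(idx, fill_value=False).astype(bool)
    )


def dose_confirmation(
    readouts_by_dose: pd.DataFrame,
    control_readouts,
    model_readouts,
    control_level: float = 0.95,
    model_tail: float = 0.05,
    min_doses: int = 2,
) -> pd.DataFrame:
    """Confirm hits across concentrations.

    ``readouts_by_dose`` is compounds x concentrations.  A compound is
    confirmed when the cumulative hit criterion holds at >=
    ``min_doses`` concentrations; the Spearman rank correlation of
    readout vs concentration summarizes the dose trend.
    """
    if readouts_by_dose.shape[1] < 2:
        raise ValueError("need readouts at >= 2 concentrations")
    rows = {}
    for cid, row in readouts_by_dose.iterrows():
        vals = row.dropna()
        cats = qc_mod.cumulative_hit_filter(
            pd.Series(vals.to_numpy(), index=vals.index),
            control_readouts,
            model_readouts,
            control_level=control_level,
            model_tail=model_tail,
        )
        n_hit = int(cats["hit"].sum())
        if vals.size >= 2 and np.ptp(vals.to_numpy()) > 0:
            rho = float(stats.spearmanr(vals.index.to_numpy(dtype=float), vals.to_numpy()).statistic)
        else:
            rho = 0.0
        rows[cid] = {"n_doses_hit": n_hit, "confirmed": n_hit >= min_doses, "trend_rho": rho}
    return pd.DataFrame(rows).T


def run_screen(
    dataset: ScreenDataset,
    model: TrainedClassifier,
    *,
    feature_names=DEFAULT_PROFILE_FEATURES,
    confirmation_concs=CONFIRMATION_CONCS_UM,
    z_prime_min: float = 0.5,
    control_level: float = 0.95,
    model_tail: float = 0.05,
    membership_quantile: float = 0.975,
    confirm_final: bool = False,
) -> ScreenResult:
    """Run the full two-step screen on a (simulated) dataset.

    Wells on plates failing Z' QC never contribute to hit calls.
    Confirmation-dose wells are simulated only for step-1 passers (the
    funnel the assay actually runs).
    """
    readouts = compute_well_readouts(dataset)
    plate_qcs = run_plate_qc(readouts, z_prime_min=z_prime_min)
    passing = {q.plate_id for q in plate_qcs if q.pass_flag}
    ok = readouts[readouts["plate_id"].isin(passing)]

    ctrl_read = ok.loc[ok["role"] == "control", "relative_count"].dropna().to_numpy()
    model_read = ok.loc[ok["role"] == "model", "relative_count"].dropna().to_numpy()
    comp = ok[ok["role"] == "compound"].dropna(subset=["relative_count"])
    comp_readouts = pd.Series(
        comp["relative_count"].to_numpy(), index=comp["compound_id"].to_numpy()
    )

    # --- step 1: classifier gate on the decision-time frame
    types_by_compound: dict[str, list[int]] = {}
    for rec in dataset.wells_of(role="compound"):
        if rec.plate_id not in passing:
            continue
        frame = dataset.images[rec.well_id][-1]
        label, _ = classify(model, frame)
        types_by_compound.setdefault(rec.compound_id, []).append(label)
    step1 = step1_classifier_gate(types_by_compound)
    decision_type = pd.Series(
        {c: majority_type(t) for c, t in types_by_compound.items()}, dtype=int
    )

    # --- cumulative filter at the primary concentration
    cumulative = qc_mod.cumulative_hit_filter(
        comp_readouts, ctrl_read, model_read,
        control_level=control_level, model_tail=model_tail,
    )

    # --- step 2: confirmation-dose profiles, simulated only for
    # compounds still alive in the funnel (step-1 pass AND cumulative
    # hit; the PCA criterion cannot rescue a compound failing either)
    alive = step1 & cumulative["hit"].reindex(step1.index, fill_value=False)
    step1_passers = sorted(alive.index[alive])
    profiles_by_dose: dict[float, pd.DataFrame] = {}
    conf_readouts = pd.DataFrame(
        index=step1_passers, columns=list(confirmation_concs), dtype=float
    )
    if step1_passers:
        conf_recs, conf_imgs, _ = simulate_confirmation(
            dataset, step1_passers, concs_um=confirmation_concs
        )
        params = segmentation_params(dataset.render_scale)
        for conc in confirmation_concs:
            recs = [r for r in conf_recs if r.conc_um == conc]
            profiles_by_dose[conc] = compound_profiles(
                dataset, recs, conf_imgs, feature_names, index_by="compound_id"
            )
            for r in recs:
                frames = conf_imgs[r.well_id]
                counts = [
                    count_cells(segment_cells(f, "dpc", **params)) for f in frames
                ]
                if counts[0] > 0:
                    conf_readouts.loc[r.compound_id, conc] = counts[-1] / counts[0]

    ctrl_recs = [r for r in dataset.wells_of(role="control") if r.plate_id in passing]
    control_prof = compound_profiles(dataset, ctrl_recs, dataset.images, feature_names)
    step2, membership = step2_morphology_gate(
        cumulative, profiles_by_dose, control_prof,
        membership_quantile=membership_quantile,
    )
    final = final_hit_call(step1, step2)

    confirmed = pd.DataFrame(columns=["n_doses_hit", "confirmed", "trend_rho"])
    if confirm_final and final.any():
        confirmed = dose_confirmation(
            conf_readouts.loc[final.index[final].intersection(conf_readouts.index)],
            ctrl_read, model_read,
            control_level=control_level, model_tail=model_tail,
        )

    table = pd.DataFrame(index=final.index)
    table["classifier_type_24h"] = decision_type.reindex(final.index)
    table["phenotype_group"] = table["classifier_type_24h"].map(
        lambda t: group_type(int(t)) if pd.notna(t) else ""
    )
    table["readout"] = comp_readouts.reindex(final.index)
    table["cumulative_category"] = cumulative["category"].reindex(final.index)
    table["cumulative_flag"] = cumulative["hit"].reindex(final.index, fill_value=False)
    table["pca_control_membership"] = membership.any(axis=1).reindex(
        final.index, fill_value=False
    )
    table["step1_pass"] = step1.reindex(final.index, fill_value=False)
    table["step2_pass"] = step2.reindex(final.index, fill_value=False)
    table["final_hit"] = final
    table["dose_confirmed"] = (
        confirmed["confirmed"].reindex(final.index, fill_value=False)
        if len(confirmed)
        else False
    )
    funnel = {
        "n_compounds": int(len(final)),
        "n_plates": len(plate_qcs),
        "n_plates_passing_qc": len(passing),
        "step1_pass": int(step1.sum()),
        "step2_pass": int(step2.sum()),
        "final_hits": int(final.sum()),
    }
    return ScreenResult(
        table=table, plate_qc=plate_qcs, funnel=funnel, well_readouts=readouts
    )
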