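"""Model evaluation: curve errors and clinical-agreement analysis.

Predicted IA curves are unscaled back to degrees, their rates of change are
obtained by finite differences of consecutive predicted IAs (the same
estimator the derivative-weighted loss uses), and the same 48 discrete
balance variables extracted from the ground truth are extracted from the
predictions.  Agreement between the model's between-group statistics and
the ground truth's is summarized per the published framework (false
negatives/positives, sensitivity, specificity, accuracy, Pearson's r of
effect sizes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clinstat
from .balance import BalanceCurves
from .imuprep import ChannelScaler, NormalizedTrial
from .rnn import BalanceRNN
from .train import finite_diff

__all__ = [
    "predict_curves",
    "curve_error_table",
    "model_variable_table",
    "evaluate_agreement",
    "subject_rmse_vectors",
]


def predict_curves(
    model: BalanceRNN,
    trials: list[NormalizedTrial],
    scaler: ChannelScaler,
) -> list[BalanceCurves]:
    """Predicted IA (deg) and finite-difference RCIA (deg/s) per trial."""
    X = np.stack([scaler.scale_inputs(t.imu) for t in trials])
    pred_scaled = model.predict(X)
    out = []
    for trial, pred in zip(trials, pred_scaled):
        ia = scaler.unscale_outputs(pred)
        dt = trial.cycle_duration_s / 100.0
        rcia = finite_diff(ia, dt)
        out.append(BalanceCurves(ia[0], ia[1], rcia[0], rcia[1]))
    return out


def curve_error_table(
    model: BalanceRNN,
    trials: list[NormalizedTrial],
    scaler: ChannelScaler,
) -> pd.DataFrame:
    """Per-trial RMSE (deg, deg/s) and rRMSE (%) for IA and RCIA curves."""
    rows = []
    for trial, pred in zip(trials, predict_curves(model, trials, scaler)):
        ia_rmse = clinstat.rmse_curves(pred.ia, trial.target_ia)
        ia_rrmse = clinstat.rrmse_curves(pred.ia, trial.target_ia)
        rc_rmse = clinstat.rmse_curves(pred.rcia, trial.target_rcia)
        rc_rrmse = clinstat.rrmse_curves(pred.rcia, trial.target_rcia)
        rows.append({
            "subject_id": trial.subject_id, "trial_id": trial.trial_id,
            "group": trial.group,
            "rmse_ia_sag": ia_rmse[0], "rmse_ia_fro": ia_rmse[1],
            "rrmse_ia_sag": ia_rrmse[0], "rrmse_ia_fro": ia_rrmse[1],
            "rmse_rcia_sag": rc_rmse[0], "rmse_rcia_fro": rc_rmse[1],
            "rrmse_rcia_sag": rc_rrmse[0], "rrmse_rcia_fro": rc_rrmse[1],
        })
    return pd.DataFrame(rows)


def subject_rmse_vectors(error_table: pd.DataFrame, column: str) -> pd.Series:
    """Per-subject mean of one error column (for paired model comparisons)."""
    return error_table.groupby("subject_id")[column].mean()


def model_variable_table(
    model: BalanceRNN,
    trials: list[NormalizedTrial],
    scaler: ChannelScaler,
) -> clinstat.VariableTable:
    """48 balance variables per subject from model-predicted curves."""
    preds = predict_curves(model, trials, scaler)
    per_subject: dict[str, tuple[str, list]] = {}
    for trial, pred in zip(trials, preds):
        group, lst = per_subject.setdefault(trial.subject_id,
                                            (trial.group, []))
        lst.append((pred, trial.events))
    return clinstat.VariableTable.from_subject_curves(per_subject)


def evaluate_agreement(
    model: BalanceRNN,
    trials: list[NormalizedTrial],
    scaler: ChannelScaler,
    truth_table: clinstat.VariableTable,
    alpha: float = 0.05,
) -> tuple[clinstat.AgreementReport, clinstat.GroupComparison, clinstat.GroupComparison]:
    """Agreement of model-predicted between-group statistics with the truth.

    The ground-truth comparison uses the full cohort's variable table; the
    model comparison uses the subjects present in ``trials``, restricted to
    the same subject set on both sides.
    """
    model_table = model_variable_table(model, trials, scaler)
    subjects = model_table.values.index
    truth_sub = clinstat.VariableTable(
        values=truth_table.values.loc[subjects],
        groups=truth_table.groups.loc[subjects])
    truth_cmp = clinstat.group_comparison(truth_sub, alpha=alpha)
    model_cmp = clinstat.group_comparison(model_table, alpha=alpha)
    return clinstat.agreement(model_cmp, truth_cmp), model_cmp, truth_cmp
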