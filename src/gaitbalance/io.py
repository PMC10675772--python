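"""Plain-text serialization of cohorts, tables, and model checkpoints.

A cohort directory contains one sub-directory per subject with one
tab-separated file per trial (documented header: channel, unit, rate), a
``manifest.tsv`` with per-trial metadata, the ground-truth variable table,
and the generating spec as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import GaitEvents, N_CYCLE
from .clinstat import AgreementReport, GroupComparison, VariableTable
from .imuprep import IMU_CHANNELS, NormalizedTrial
from .rnn import BalanceRNN, ModelConfig
from .synth import Cohort, CohortSpec

__all__ = [
    "write_cohort", "read_cohort",
    "save_model", "load_model",
    "write_group_comparison", "write_agreement",
]

_TRIAL_COLUMNS = (
    [f"{c}_filt" for c in IMU_CHANNELS]
    + ["sagittal_ia_deg", "frontal_ia_deg",
       "sagittal_rcia_dps", "frontal_rcia_dps"]
)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as per-subject directories of columnar text files."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "cohort_spec.yaml").write_text(
        yaml.safe_dump({**asdict(cohort.spec),
                        "event_pcts": list(cohort.spec.event_pcts),
                        "effect_spec": [list(e) for e in cohort.spec.effect_spec]}))
    manifest = []
    for trial in cohort.trials:
        sub_dir = root / trial.subject_id
        sub_dir.mkdir(exist_ok=True)
        df = pd.DataFrame(
            np.vstack([trial.imu, trial.target_ia, trial.target_rcia]).T,
            columns=_TRIAL_COLUMNS)
        df.insert(0, "pct_cycle", np.arange(N_CYCLE))
        fn = sub_dir / f"{trial.trial_id}.tsv"
        with open(fn, "w") as fh:
            fh.write("# filtered IMU (m/s^2, deg/s) and balance curves over "
                     "the normalized gait cycle (101 points)\n")
            df.to_csv(fh, sep="\t", index=False)
        manifest.append({
            "subject_id": trial.subject_id, "trial_id": trial.trial_id,
            "group": trial.group, "stance_side": trial.stance_side,
            "file": str(fn.relative_to(root)),
            "cycle_duration_s": trial.cycle_duration_s,
            "cto_pct": trial.events.cto_pct, "chs_pct": trial.events.chs_pct,
            "to_pct": trial.events.to_pct,
        })
    pd.DataFrame(manifest).to_csv(root / "manifest.tsv", sep="\t", index=False)
    vt = cohort.variable_table
    table = vt.values.copy()
    table.insert(0, "group", vt.groups)
    table.to_csv(root / "variable_table.tsv", sep="\t",
                 index_label="subject_id")
    return root


def read_cohort(path: str | Path) -> Cohort:
    root = Path(path)
    spec_dict = yaml.safe_load((root / "cohort_spec.yaml").read_text())
    spec_dict["event_pcts"] = tuple(spec_dict["event_pcts"])
    spec_dict["effect_spec"] = tuple(tuple(e) for e in spec_dict["effect_spec"])
    spec = CohortSpec(**spec_dict)
    manifest = pd.read_csv(root / "manifest.tsv", sep="\t")
    trials = []
    for rec in manifest.itertuples():
        df = pd.read_csv(root / rec.file, sep="\t", comment="#")
        arr = df[_TRIAL_COLUMNS].to_numpy().T
        events = GaitEvents.from_pct(rec.cto_pct, rec.chs_pct, rec.to_pct,
                                     cycle_duration_s=rec.cycle_duration_s)
        trials.append(NormalizedTrial(
            imu=arr[:6], target_ia=arr[6:8], target_rcia=arr[8:10],
            events=events, cycle_duration_s=rec.cycle_duration_s,
            subject_id=rec.subject_id, group=rec.group,
            trial_id=rec.trial_id, stance_side=rec.stance_side))
    table = pd.read_csv(root / "variable_table.tsv", sep="\t",
                        index_col="subject_id")
    groups = table.pop("group")
    table.columns = table.columns.astype(int)
    return Cohort(spec=spec, trials=trials,
                  variable_table=VariableTable(values=table, groups=groups))


def save_model(model: BalanceRNN, path: str | Path) -> None:
    """Checkpoint: config + named parameter arrays in one npz archive."""
    cfg = model.config
    meta = dict(cell_type=cfg.cell_type, bidirectional=int(cfg.bidirectional),
                profile=cfg.profile, hidden_sizes=list(cfg.hidden_sizes),
                input_channels=cfg.input_channels, seq_len=cfg.seq_len,
                output_planes=cfg.output_planes)
    np.savez(path, __config__=json.dumps(meta), **model.parameters())


def load_model(path: str | Path) -> BalanceRNN:
    with np.load(path) as data:
        meta = json.loads(str(data["__config__"]))
        cfg = ModelConfig(
            cell_type=meta["cell_type"], bidirectional=bool(meta["bidirectional"]),
            profile=meta["profile"], hidden_sizes=tuple(meta["hidden_sizes"]),
            input_channels=meta["input_channels"], seq_len=meta["seq_len"],
            output_planes=meta["output_planes"])
        model = BalanceRNN(cfg, seed=0)
        model.set_parameters({k: data[k] for k in data.files
                              if k != "__config__"})
    return model


def write_group_comparison(cmp_: GroupComparison, path: str | Path) -> None:
    cmp_.table.to_csv(path, sep="\t", index_label="variable")


def write_agreement(report: AgreementReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
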