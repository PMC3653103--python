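"""Plain-text I/O: trial/spike/waveform CSV dialects, ground truth, configs.

Trials: one row per trial with the columns of :data:`pptn_tonic.task.TRIAL_COLUMNS`
(absent events empty).  Spikes: long format ``neuron_id, trial_id,
spike_time_s``.  Waveforms: ``neuron_id, sample_index, amplitude``.  Ground
truth and run manifests are JSON; configs may be YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import yaml

from .neurons import NeuronProfile, NeuronRecording, PhasicComponent
from .task import TRIAL_COLUMNS


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trial columns {sorted(missing)}")
    return df


def write_spikes(spikes_by_neuron: Dict[str, Dict[int, np.ndarray]], path) -> None:
    rows = []
    for nid, by_trial in spikes_by_neuron.items():
        for tid, spk in by_trial.items():
            for t in spk:
                rows.append((nid, tid, t))
    pd.DataFrame(rows, columns=["neuron_id", "trial_id", "spike_time_s"]) \
        .to_csv(path, index=False)


def read_spikes(path) -> Dict[str, Dict[int, np.ndarray]]:
    df = pd.read_csv(path)
    need = {"neuron_id", "trial_id", "spike_time_s"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing spike columns {sorted(need - set(df.columns))}")
    out: Dict[str, Dict[int, np.ndarray]] = {}
    for (nid, tid), grp in df.groupby(["neuron_id", "trial_id"], sort=True):
        out.setdefault(str(nid), {})[int(tid)] = grp["spike_time_s"].to_numpy(dtype=float)
    return out


def write_waveforms(waveforms: Dict[str, np.ndarray], path) -> None:
    rows = []
    for nid, w in waveforms.items():
        for i, a in enumerate(np.asarray(w)):
            rows.append((nid, i, a))
    pd.DataFrame(rows, columns=["neuron_id", "sample_index", "amplitude"]) \
        .to_csv(path, index=False)


def read_waveforms(path) -> Dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {str(nid): grp.sort_values("sample_index")["amplitude"]
            .to_numpy(dtype=float)
            for nid, grp in df.groupby("neuron_id")}


def write_ground_truth(profiles: Dict[str, NeuronProfile], path) -> None:
    payload = {nid: dataclasses.asdict(p) for nid, p in profiles.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> Dict[str, NeuronProfile]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for nid, d in payload.items():
        d["phasic_components"] = tuple(PhasicComponent(**pc)
                                       for pc in d.get("phasic_components", ()))
        out[nid] = NeuronProfile(**d)
    return out


def load_config(path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def write_population(population: Sequence[tuple[NeuronRecording, NeuronProfile]],
                     outdir) -> None:
    """Write a simulated population as the CSV/JSON bundle under ``outdir``.

    Layout: ``trials/<neuron_id>.csv`` (each neuron has its own session),
    ``spikes.csv``, ``waveforms.csv``, ``ground_truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "trials").mkdir(parents=True, exist_ok=True)
    for rec, _ in population:
        write_trials(rec.trials, outdir / "trials" / f"{rec.neuron_id}.csv")
    write_spikes({rec.neuron_id: rec.spikes for rec, _ in population},
                 outdir / "spikes.csv")
    write_waveforms({rec.neuron_id: rec.waveform for rec, _ in population
                     if rec.waveform is not None}, outdir / "waveforms.csv")
    write_ground_truth({rec.neuron_id: prof for rec, prof in population},
                       outdir / "ground_truth.json")


def read_population(datadir) -> list[NeuronRecording]:
    """Read a population bundle written by :func:`write_population`."""
    datadir = Path(datadir)
    spikes = read_spikes(datadir / "spikes.csv")
    wav_path = datadir / "waveforms.csv"
    waveforms = read_waveforms(wav_path) if wav_path.exists() else {}
    recs = []
    for trial_file in sorted((datadir / "trials").glob("*.csv")):
        nid = trial_file.stem
        recs.append(NeuronRecording(
            neuron_id=nid, trials=read_trials(trial_file),
            spikes=spikes.get(nid, {}), waveform=waveforms.get(nid)))
    if not recs:
        raise FileNotFoundError(f"no trial files under {datadir / 'trials'}")
    return recs
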