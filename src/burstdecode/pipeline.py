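"""End-to-end orchestration: synthetic session -> preprocessing -> burst
detection -> trial tensors -> decoder cross-validation -> metrics.

These helpers are the programmatic counterpart of the command-line
interface and the entry points the validation studies drive.  Problem sizes
(number of lists, tensor sampling rate, training epochs) are all explicit
arguments so demonstration runs can be kept small.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import burst as burst_mod
from . import decode as decode_mod
from . import metrics as metrics_mod
from . import preprocess as pre
from . import tensorize as tz
from .simulate import SyntheticSession

__all__ = ["preprocess_session", "session_to_datasets", "decode_experiment",
           "experiment_snrs"]


def preprocess_session(session: SyntheticSession) -> np.ndarray:
    """Notch-filter, standardize and (if needed) resample to 500 Hz.

    The synthetic montage is already bipolar; on real referential recordings
    :func:`burstdecode.preprocess.to_bipolar` runs first.
    """
    sig = pre.notch_60(session.signal, session.fs_hz)
    if session.fs_hz != 500:
        sig = pre.resample_to(sig, session.fs_hz, 500)
    return pre.standardize(sig)


def session_to_datasets(session: SyntheticSession, *, tensor_fs: float = 500.0,
                        z_thresh: float = 2.0, window_s: float = 3.0,
                        per_list: int = 12, seed: int = 0,
                        bursts: pd.DataFrame | None = None) -> dict:
    """Build every labeled dataset of one experiment.

    Returns a dict with the detected ``bursts`` table and the datasets
    ``enc_burst`` (cnn2b), ``enc_broadband`` (cnn2a), ``state`` (cnn1) and
    ``recall_epoch`` (cnn3), all sampled at ``tensor_fs``.
    """
    clean = preprocess_session(session)
    if bursts is None:
        bursts = burst_mod.detect_session(clean, 500.0, z_thresh=z_thresh)
    n_out = int(round(session.duration_s * tensor_fs))
    rows = burst_mod.session_convolved_rows(bursts, session.n_channels, n_out,
                                            tensor_fs)
    row_names = []
    for ch in range(session.n_channels):
        name = (session.channel_names[ch] if session.channel_names
                else f"ch{ch}")
        row_names += [f"{name}:hg", f"{name}:beta"]

    sched = session.schedule
    enc_burst = tz.extract_encoding_epochs(sched, session.recalled, rows,
                                           tensor_fs, window_s=window_s,
                                           kind=tz.TensorKind.ENC_BURST)
    enc_burst.row_names = row_names

    broadband = pre.resample_to(clean, 500, int(tensor_fs)) \
        if tensor_fs != 500 else clean
    enc_broad = tz.extract_encoding_epochs(sched, session.recalled, broadband,
                                           tensor_fs, window_s=window_s,
                                           kind=tz.TensorKind.ENC_BROADBAND)

    recall_seg = tz.extract_recall_segments(sched, rows, tensor_fs,
                                            window_s=window_s,
                                            per_list=per_list, seed=seed)
    state = tz.build_state_dataset(enc_burst, recall_seg, seed=seed)
    state.row_names = row_names

    recall_epoch = tz.extract_recall_epochs(sched, session.recall_counts,
                                            rows, tensor_fs)
    recall_epoch.row_names = row_names
    return {"bursts": bursts, "enc_burst": enc_burst,
            "enc_broadband": enc_broad, "state": state,
            "recall_epoch": recall_epoch}


MODEL_DATASET = {"cnn1": "state", "cnn2a": "enc_broadband",
                 "cnn2b": "enc_burst", "cnn3": "recall_epoch"}


def decode_experiment(dataset: tz.LabeledDataset, model: str = "cnn2b",
                      epochs: int | None = None, k: int | None = None,
                      seed: int = 0) -> dict:
    """Cross-validate one decoder and summarize its pooled ROC."""
    config = decode_mod.MODEL_CONFIGS[model].scaled(epochs)
    preds = decode_mod.crossvalidate(dataset, config, k=k, seed=seed)
    roc_auc = metrics_mod.auroc(preds.probability, preds.label)
    point = metrics_mod.youden_point(preds.probability, preds.label)
    return {"model": model, "predictions": preds, "auroc": roc_auc,
            "youden": point, "n_trials": len(preds)}


def experiment_snrs(session: SyntheticSession) -> tuple[list[float], list[float]]:
    """Per-contact high-gamma and beta burst SNRs on the physical signal."""
    hg, beta = [], []
    for ch in range(session.n_channels):
        hg.append(burst_mod.burst_snr(session.signal[ch], session.fs_hz, "hg"))
        beta.append(burst_mod.burst_snr(session.signal[ch], session.fs_hz, "beta"))
    return hg, beta
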