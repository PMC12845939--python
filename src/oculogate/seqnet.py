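"""Optional conv-recurrent sequence classifier over derived-signal windows.

The classifier consumes 2-channel windows (pupil percent-change and gaze
speed) covering one 13 s stimulus block (last 3 s of baseline + 8 s stimulus
+ 2 s of rest), not raw video.  Architecture: three 1-D convolutional blocks
(16/32/64 filters, kernel 7, stride 2, batch norm, ReLU) followed by two
stacked LSTM layers of 128 units and a 2-class softmax head; trained with
Adam (lr 2e-4), batch 32, up to 60 epochs with early stopping (patience 10)
on a participant-level 70/15/15 split.

Window construction and participant-level aggregation are plain numpy and
always available; training requires the optional ``torch`` extra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SeqClassifierConfig", "build_windows", "aggregate_by_participant",
           "participant_split", "train_seq_classifier", "predict"]


@dataclass
class SeqClassifierConfig:
    window_s: float = 13.0
    sampling_rate: float = 100.0
    conv_filters: tuple[int, int, int] = (16, 32, 64)
    conv_kernel: int = 7
    conv_stride: int = 2
    lstm_layers: int = 2
    lstm_units: int = 128
    learning_rate: float = 2e-4
    epochs: int = 60
    batch_size: int = 32
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sampling_rate))


def build_windows(trace: pd.DataFrame, schedule, clean=None,
                  cfg: SeqClassifierConfig | None = None) -> np.ndarray:
    """Per-stimulus 2-channel windows, shape (n_stimuli, 2, window_samples).

    Channel 0: pupil percent change relative to the block's pre-stimulus
    baseline mean; channel 1: gaze speed (deg/s).  Windows start 3 s before
    stimulus onset and are cropped/zero-padded to the configured length.
    """
    from .oculometrics import preprocess

    cfg = cfg or SeqClassifierConfig()
    cl = clean if clean is not None else preprocess(trace)
    n = cfg.window_samples
    out = np.zeros((len(schedule.blocks), 2, n))
    for i, block in enumerate(schedule.blocks):
        t0 = block.onset_ms - 3000.0
        m = (cl.t_ms >= t0) & (cl.t_ms < t0 + cfg.window_s * 1000.0)
        base_m = (cl.t_ms >= block.onset_ms - 3000.0) & (cl.t_ms < block.onset_ms)
        b = np.nanmean(cl.pupil[base_m]) if np.isfinite(cl.pupil[base_m]).any() else np.nan
        pct = 100.0 * (cl.pupil[m] - b) / b if np.isfinite(b) else np.zeros(m.sum())
        spd = cl.speed[m]
        k = min(n, m.sum())
        out[i, 0, :k] = np.nan_to_num(pct[:k], nan=0.0)
        out[i, 1, :k] = np.nan_to_num(spd[:k], nan=0.0)
    return out


def aggregate_by_participant(stimulus_probs, participant_ids) -> pd.Series:
    """Participant-level probability: mean of the per-stimulus probabilities."""
    return (pd.Series(np.asarray(stimulus_probs, dtype=float),
                      index=list(participant_ids))
            .groupby(level=0).mean())


def participant_split(participant_ids, split=(0.70, 0.15, 0.15), seed: int = 0
                      ) -> dict[str, list]:
    """Shuffle participants (never stimuli) into train/val/test groups, so no
    stimulus of a test participant ever leaks into training."""
    ids = sorted(set(participant_ids))
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    rng.shuffle(ids)
    n = len(ids)
    n_tr = int(round(split[0] * n))
    n_va = int(round(split[1] * n))
    return {"train": ids[:n_tr], "val": ids[n_tr:n_tr + n_va],
            "test": ids[n_tr + n_va:]}


def _require_torch():
    try:
        import torch  # noqa: F401
        return torch
    except ImportError as exc:
        raise RuntimeError(
            "the sequence classifier requires the optional 'torch' extra "
            "(pip install oculogate[torch]); the rule-based and logistic "
            "screeners do not need it") from exc


def train_seq_classifier(windows: np.ndarray, labels: np.ndarray,
                         participant_ids, cfg: SeqClassifierConfig | None = None):
    """Train the conv-recurrent classifier under the configured protocol.

    Raises RuntimeError when torch is not installed.
    """
    torch = _require_torch()
    import torch.nn as nn

    cfg = cfg or SeqClassifierConfig()
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    torch.manual_seed(cfg.seed)

    class ConvRecurrent(nn.Module):
        def __init__(self):
            super().__init__()
            layers, ch = [], 2
            for f in cfg.conv_filters:
                layers += [nn.Conv1d(ch, f, cfg.conv_kernel, stride=cfg.conv_stride,
                                     padding=cfg.conv_kernel // 2),
                           nn.BatchNorm1d(f), nn.ReLU()]
                ch = f
            self.conv = nn.Sequential(*layers)
            self.lstm = nn.LSTM(ch, cfg.lstm_units, num_layers=cfg.lstm_layers,
                                batch_first=True)
            self.head = nn.Linear(cfg.lstm_units, 2)

        def forward(self, x):
            z = self.conv(x).transpose(1, 2)
            z, _ = self.lstm(z)
            return self.head(z[:, -1])

    groups = participant_split(participant_ids, cfg.split, cfg.seed)
    pid = np.asarray(list(participant_ids))
    tr = np.isin(pid, groups["train"])
    va = np.isin(pid, groups["val"])
    xt = torch.tensor(windows[tr], dtype=torch.float32)
    yt = torch.tensor(labels[tr], dtype=torch.long)
    xv = torch.tensor(windows[va], dtype=torch.float32)
    yv = torch.tensor(labels[va], dtype=torch.long)

    model = ConvRecurrent()
    opt = torch.optim.Adam(model.parameters(), lr=cfg.learning_rate)
    lossfn = nn.CrossEntropyLoss()
    best, best_state, stall = np.inf, None, 0
    for _ in range(cfg.epochs):
        model.train()
        perm = torch.randperm(len(xt))
        for i in range(0, len(xt), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            opt.zero_grad()
            loss = lossfn(model(xt[idx]), yt[idx])
            loss.backward()
            opt.step()
        model.eval()
        with torch.no_grad():
            vloss = float(lossfn(model(xv), yv))
        if vloss < best - 1e-6:
            best, stall = vloss, 0
            best_state = {k: v.clone() for k, v in model.state_dict().items()}
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model


def predict(model, windows: np.ndarray, participant_ids=None):
    """Per-stimulus depressive-pattern probabilities; aggregated per
    participant by the mean when ids are supplied."""
    torch = _require_torch()
    with torch.no_grad():
        logits = model(torch.tensor(np.asarray(windows), dtype=torch.float32))
        probs = torch.softmax(logits, dim=1)[:, 1].numpy()
    if participant_ids is None:
        return probs
    return aggregate_by_participant(probs, participant_ids)
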