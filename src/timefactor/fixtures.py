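"""Synthetic study-scale fixtures: zebra-finch-like motif timing models.

Preset parameter values emulate adult zebra finch song at the scale the
model was built for: syllable means of roughly 50-200 msec with gaps about
half as long, per-interval total SDs of about 1.5-3.5 msec, all tempo
weights positive, component SDs (global / independent / jitter) each on the
order of 0.5-2.3 msec, gaps more tempo-elastic than syllables, and the
inter-motif gap carrying extra independent variability.  The ``two_factor``
preset adds a second, syllable/gap-antagonistic global factor (syllables
lengthen at the expense of gaps) of the kind that shows up as a
length-neutral residual factor.
"""

from __future__ import annotations

import numpy as np

from .model import IntervalDataset, LatentDraws, TimingModel, sample_dataset

__all__ = [
    "PRESETS",
    "make_fixture",
    "fixture_model",
    "paper_scale_truth",
    "paper_scale_two_factor_truth",
]

_S, _GW, _GB = "syllable", "gap_within", "gap_between"


def _zf_small() -> tuple[TimingModel, list[str]]:
    labels = [_S, _GW, _S, _GW, _S]
    means = [120.0, 55.0, 90.0, 45.0, 150.0]
    w = [1.0, 0.7, 0.9, 0.6, 1.2]
    sd_e = [1.0, 0.9, 1.2, 0.8, 1.3]
    sd_x = [0.9, 0.8, 0.85, 0.9]
    return (
        TimingModel(np.asarray(w), np.square(sd_e), np.square(sd_x), np.asarray(means)),
        labels,
    )


def _zf_song() -> tuple[TimingModel, list[str]]:
    labels = [_S, _GW, _S, _GW, _S, _GW, _S, _GW, _S, _GB, _S]
    means = [95.0, 42.0, 130.0, 55.0, 70.0, 38.0, 160.0, 48.0, 110.0, 65.0, 95.0]
    w = [1.1, 0.75, 1.3, 0.85, 0.9, 0.7, 1.4, 0.8, 1.05, 1.0, 1.1]
    sd_e = [1.1, 0.8, 1.3, 0.9, 1.0, 0.75, 1.4, 0.85, 1.2, 2.0, 1.1]
    sd_x = [0.9, 0.85, 1.0, 0.8, 0.95, 0.9, 1.05, 0.85, 1.1, 0.9]
    return (
        TimingModel(np.asarray(w), np.square(sd_e), np.square(sd_x), np.asarray(means)),
        labels,
    )


def _two_factor() -> tuple[TimingModel, list[str]]:
    base, labels = _zf_song()
    second = np.asarray([0.5 if lab == _S else -0.5 for lab in labels])
    W = np.column_stack([base.global_weights[:, 0], second])
    return (
        TimingModel(W, base.independent_vars, base.jitter_vars, base.means),
        labels,
    )


PRESETS = {
    "zf_small": (_zf_small, 400),
    "zf_song": (_zf_song, 600),
    "two_factor": (_two_factor, 800),
}


def fixture_model(preset: str) -> tuple[TimingModel, list[str]]:
    """The (deterministic) truth model and interval labels for a preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    builder, _ = PRESETS[preset]
    return builder()


def make_fixture(
    preset: str, seed: int = 0, n_trials: int | None = None
) -> tuple[TimingModel, IntervalDataset, LatentDraws]:
    """A preset truth model plus one dataset sampled from it.

    The model parameters are fixed by the preset; ``seed`` governs only the
    sampled dataset.  Default trial counts sit inside the 215-885 range of
    the song samples the scale emulates.
    """
    model, labels = fixture_model(preset)
    if n_trials is None:
        n_trials = PRESETS[preset][1]
    data, draws = sample_dataset(model, n_trials, seed=seed, interval_labels=labels)
    return model, data, draws


def paper_scale_truth() -> tuple[TimingModel, list[str]]:
    """A K=7, M=1 truth with weights and component SDs near 1 msec.

    This is the canonical Monte Carlo ground truth: small enough to refit
    hundreds of times, with every parameter class at a comparable (about
    1 msec) scale so recovery errors are directly comparable across
    classes.
    """
    labels = [_S, _GW, _S, _GW, _S, _GW, _S]
    means = [100.0, 50.0, 120.0, 60.0, 80.0, 45.0, 140.0]
    w = [1.0, 0.8, 1.2, 0.9, 1.1, 0.7, 1.0]
    sd_e = [1.0, 0.9, 1.1, 0.8, 1.0, 0.85, 1.2]
    sd_x = [1.0, 0.9, 1.1, 0.85, 0.95, 1.0]
    return (
        TimingModel(np.asarray(w), np.square(sd_e), np.square(sd_x), np.asarray(means)),
        labels,
    )


def paper_scale_two_factor_truth() -> tuple[TimingModel, list[str]]:
    """The K=7 Monte Carlo truth plus an antagonistic second global factor.

    The second factor stretches syllables while compressing gaps (weights
    +-0.5 msec), the length-neutral kind of pattern that shows up as a
    residual global factor beyond tempo.
    """
    base, labels = paper_scale_truth()
    second = np.asarray([0.5 if lab == _S else -0.5 for lab in labels])
    W = np.column_stack([base.global_weights[:, 0], second])
    return TimingModel(W, base.independent_vars, base.jitter_vars, base.means), labels
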