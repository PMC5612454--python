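"""Phone-specific dynamic model RDMs from triphone log-likelihood streams.

A speech recognizer's acoustic model emits, every 10 ms frame, a
log-likelihood for each triphone (a centre phone with its left and right
context).  Grouping triphone columns by centre phone and concatenating the
frames inside a 60 ms sliding window yields, per word and window position,
a likelihood vector that serves as that phone model's representation of the
word.  Correlation distances between those vectors across word pairs give
one model RDM per phone per window — a dynamic RDM (dRDM) per phone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ssrsa.core_rdm import ConditionSet, DynamicRDM, rdm_from_response_matrix

logger = logging.getLogger(__name__)


class EmptyModelError(ValueError):
    """A phone has no triphone with it in the centre position."""


@dataclass(frozen=True)
class TriphoneLabel:
    """A context-dependent phone unit: centre phone with left/right context."""

    left: str
    centre: str
    right: str

    def __str__(self) -> str:  # HTK-style notation
        return f"{self.left}-{self.centre}+{self.right}"


@dataclass(frozen=True)
class LikelihoodStreamSet:
    """Frame x triphone log-likelihood matrices, one per condition (word).

    All streams share the same triphone column ordering and frame count
    (e.g. 27 frames for a 270 ms epoch at a 10 ms frame step).
    """

    conditions: ConditionSet
    triphones: tuple[TriphoneLabel, ...]
    values: np.ndarray = field(repr=False)  # (n_cond, n_frames, n_triphones)
    frame_ms: int = 10

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(
                "values must be (condition, frame, triphone) 3-D array"
            )
        if v.shape[0] != self.conditions.n:
            raise ValueError("first axis must match the condition count")
        if v.shape[2] != len(self.triphones):
            raise ValueError("third axis must match the triphone count")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "triphones", tuple(self.triphones))

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def epoch_ms(self) -> int:
        return self.n_frames * self.frame_ms

    def stream(self, condition: str) -> np.ndarray:
        """Frame x triphone matrix for one condition."""
        return self.values[self.conditions.index_of(condition)]


@dataclass(frozen=True)
class PhoneModelSet:
    """The dynamic model RDMs for every modelled phone."""

    phones: tuple[str, ...]
    drdms: Mapping[str, DynamicRDM]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phones", tuple(self.phones))
        if set(self.phones) != set(self.drdms):
            raise ValueError("phones and drdms keys must match")
        if not self.phones:
            raise ValueError("PhoneModelSet needs at least one phone")
        first = self.drdms[self.phones[0]]
        for p in self.phones:
            d = self.drdms[p]
            if d.conditions.labels != first.conditions.labels:
                raise ValueError(f"phone {p}: mismatched conditions")
            if d.n_frames != first.n_frames:
                raise ValueError(f"phone {p}: mismatched frame count")

    @property
    def conditions(self) -> ConditionSet:
        return self.drdms[self.phones[0]].conditions

    @property
    def n_windows(self) -> int:
        return self.drdms[self.phones[0]].n_frames

    @property
    def total_frames(self) -> int:
        """Total model RDM frames: phones x window positions."""
        return len(self.phones) * self.n_windows


def central_phone_columns(
    streams: LikelihoodStreamSet, phone: str
) -> np.ndarray:
    """Column indices of all triphones whose centre phone is `phone`.

    Order follows the stream set's triphone ordering (deterministic).
    """
    idx = np.array(
        [k for k, t in enumerate(streams.triphones) if t.centre == phone],
        dtype=np.intp,
    )
    if idx.size == 0:
        raise EmptyModelError(
            f"phone '{phone}' never occurs as a triphone centre; no model "
            "RDM can be built for it"
        )
    return idx


def windowed_likelihood_vector(
    stream: np.ndarray,
    columns: np.ndarray,
    window_onset_ms: int,
    *,
    window_ms: int = 60,
    frame_ms: int = 10,
) -> np.ndarray:
    """Concatenate selected likelihood columns over one sliding window.

    `stream` is a frame x triphone matrix.  The window covers
    [onset, onset + window_ms) and must lie inside the epoch.  Frames are
    concatenated frame-major (all selected columns of frame k, then frame
    k+1, ...); correlation distance is invariant to this order, which is
    fixed for reproducibility only.  Length is (window_ms/frame_ms) x
    |columns| — six frames per 60 ms window at the 10 ms frame step.
    """
    if window_onset_ms < 0 or window_onset_ms % frame_ms != 0:
        raise ValueError(
            f"window onset {window_onset_ms} ms must be a non-negative "
            f"multiple of the frame step ({frame_ms} ms)"
        )
    f0 = window_onset_ms // frame_ms
    n_win_frames = window_ms // frame_ms
    if f0 + n_win_frames > stream.shape[0]:
        raise ValueError(
            f"window [{window_onset_ms}, {window_onset_ms + window_ms}) ms "
            f"extends past the {stream.shape[0] * frame_ms} ms epoch"
        )
    block = stream[f0 : f0 + n_win_frames][:, columns]
    return block.reshape(-1)  # row-major flatten = frame-major order


def build_phone_drdm(
    streams: LikelihoodStreamSet,
    phone: str,
    window_onsets: Sequence[int],
    *,
    window_ms: int = 60,
) -> DynamicRDM:
    """One model RDM per window onset for a single phone.

    Entry (i, j) of the RDM at window w is the correlation distance between
    the windowed likelihood vectors of conditions i and j.
    """
    cols = central_phone_columns(streams, phone)
    n_win_frames = window_ms // streams.frame_ms
    frames = []
    for onset in window_onsets:
        f0 = onset // streams.frame_ms
        if onset < 0 or onset % streams.frame_ms or (
            f0 + n_win_frames > streams.n_frames
        ):
            raise ValueError(
                f"invalid window onset {onset} ms for a "
                f"{streams.epoch_ms} ms epoch"
            )
        # (n_cond, n_win_frames, |cols|) -> frame-major flattened rows
        block = streams.values[:, f0 : f0 + n_win_frames, :][:, :, cols]
        resp = block.reshape(streams.conditions.n, -1)
        try:
            frames.append(rdm_from_response_matrix(resp, streams.conditions))
        except Exception as e:
            raise type(e)(
                f"phone '{phone}', window onset {onset} ms: {e}"
            ) from e
    step = (
        int(window_onsets[1] - window_onsets[0])
        if len(window_onsets) > 1
        else streams.frame_ms
    )
    return DynamicRDM(tuple(frames), window_ms=window_ms, step_ms=step)


def build_model_set(
    streams: LikelihoodStreamSet,
    inventory: Sequence[str],
    window_onsets: Sequence[int],
    *,
    window_ms: int = 60,
) -> PhoneModelSet:
    """Build dRDMs for every phone in the inventory with >= 1 triphone.

    Phones never occurring as a triphone centre get no model; they are
    logged and excluded (mirroring restriction to the phones actually
    present in the stimulus set) rather than raising.
    """
    drdms: dict[str, DynamicRDM] = {}
    dropped = []
    for phone in inventory:
        try:
            drdms[phone] = build_phone_drdm(
                streams, phone, window_onsets, window_ms=window_ms
            )
        except EmptyModelError:
            dropped.append(phone)
    if dropped:
        msg = (
            f"dropped {len(dropped)} phone(s) with no central-position "
            f"triphone: {', '.join(dropped)}"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not drdms:
        raise EmptyModelError("no phone in the inventory has any triphone")
    return PhoneModelSet(tuple(drdms), drdms)


def triphone_capacity(inventory: Sequence[str]) -> int:
    """Maximum number of distinct triphone units over a phone inventory.

    Every (left, centre, right) triple is a possible unit, so the capacity
    is the cube of the inventory size (85,184 for 44 phones).
    """
    n = len(set(inventory))
    return n ** 3


def acoustic_vector_dim(
    n_cepstra: int = 12,
    *,
    include_energy: bool = True,
    n_derivative_orders: int = 2,
) -> int:
    """Dimension of the per-frame acoustic feature vector of the recognizer.

    The standard front end represents each 10 ms frame by `n_cepstra`
    mel-frequency cepstral coefficients plus an energy term, together with
    first and second time derivatives of the whole block: (12 + 1) x 3 = 39
    by default.  Provided as metadata; this package does not compute MFCCs.
    """
    base = n_cepstra + (1 if include_energy else 0)
    return base * (1 + n_derivative_orders)
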