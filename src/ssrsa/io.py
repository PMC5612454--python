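"""Hierarchical-container (HDF5) and tabular persistence.

Layout conventions:

* model RDM stacks:   /model/<phone>/frame<k>   (n x n float64)
* data RDM stacks:    /data/<vertex>/frame<k>
* likelihood streams: /streams/<condition> (frame x triphone float64)
                      plus a /triphones table of (left, centre, right)
* source epochs:      /epochs/<subject>/<condition> (vertex x time)
* null samples:       /null/<feature>/samples

Condition labels travel as a string attribute table on the file root so
that round trips preserve the ConditionSet.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from ssrsa.brain_states import SourceEpochSet
from ssrsa.core_rdm import ConditionSet, DynamicRDM, RDM
from ssrsa.machine_states import (
    LikelihoodStreamSet,
    PhoneModelSet,
    TriphoneLabel,
)
from ssrsa.permutation_stats import FeatureFitMap, NullDistribution

_STR = h5py.string_dtype(encoding="utf-8")


def _write_conditions(f: h5py.File, cs: ConditionSet) -> None:
    f.attrs["conditions"] = np.array(cs.labels, dtype=_STR)


def _read_conditions(f: h5py.File) -> ConditionSet:
    labels = [
        s.decode() if isinstance(s, bytes) else str(s)
        for s in f.attrs["conditions"]
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ConditionSet(labels)


def _write_drdm(group: h5py.Group, drdm: DynamicRDM) -> None:
    group.attrs["window_ms"] = drdm.window_ms
    group.attrs["step_ms"] = drdm.step_ms
    for k, frame in enumerate(drdm.frames):
        group.create_dataset(f"frame{k}", data=frame.values)


def _read_drdm(group: h5py.Group, cs: ConditionSet) -> DynamicRDM:
    n = len([k for k in group if k.startswith("frame")])
    frames = tuple(RDM(cs, group[f"frame{k}"][()]) for k in range(n))
    return DynamicRDM(
        frames,
        window_ms=int(group.attrs["window_ms"]),
        step_ms=int(group.attrs["step_ms"]),
    )


def save_model_set(model_set: PhoneModelSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _write_conditions(f, model_set.conditions)
        root = f.create_group("model")
        root.attrs["phones"] = np.array(model_set.phones, dtype=_STR)
        for phone in model_set.phones:
            _write_drdm(root.create_group(phone), model_set.drdms[phone])


def load_model_set(path: str | Path) -> PhoneModelSet:
    with h5py.File(path, "r") as f:
        cs = _read_conditions(f)
        root = f["model"]
        phones = tuple(
            s.decode() if isinstance(s, bytes) else str(s)
            for s in root.attrs["phones"]
        )
        drdms = {p: _read_drdm(root[p], cs) for p in phones}
    return PhoneModelSet(phones, drdms)


def save_data_drdms(
    drdms: Mapping[int, DynamicRDM], path: str | Path
) -> None:
    if not drdms:
        raise ValueError("nothing to save")
    cs = next(iter(drdms.values())).conditions
    with h5py.File(path, "w") as f:
        _write_conditions(f, cs)
        root = f.create_group("data")
        for vertex, drdm in drdms.items():
            _write_drdm(root.create_group(str(vertex)), drdm)


def load_data_drdms(path: str | Path) -> dict[int, DynamicRDM]:
    with h5py.File(path, "r") as f:
        cs = _read_conditions(f)
        root = f["data"]
        return {int(v): _read_drdm(root[v], cs) for v in root}


def save_likelihood_streams(
    streams: LikelihoodStreamSet, path: str | Path
) -> None:
    with h5py.File(path, "w") as f:
        _write_conditions(f, streams.conditions)
        f.attrs["frame_ms"] = streams.frame_ms
        tri = np.array(
            [(t.left, t.centre, t.right) for t in streams.triphones],
            dtype=_STR,
        )
        f.create_dataset("triphones", data=tri)
        grp = f.create_group("streams")
        for i, cond in enumerate(streams.conditions.labels):
            grp.create_dataset(cond, data=streams.values[i])


def load_likelihood_streams(path: str | Path) -> LikelihoodStreamSet:
    with h5py.File(path, "r") as f:
        cs = _read_conditions(f)
        tri_raw = f["triphones"][()]
        triphones = tuple(
            TriphoneLabel(
                *(s.decode() if isinstance(s, bytes) else str(s) for s in row)
            )
            for row in tri_raw
        )
        values = np.stack([f["streams"][c][()] for c in cs.labels])
        frame_ms = int(f.attrs["frame_ms"])
    return LikelihoodStreamSet(
        conditions=cs, triphones=triphones, values=values, frame_ms=frame_ms
    )


def load_likelihood_streams_csv(path: str | Path) -> LikelihoodStreamSet:
    """Read long-format CSV (condition, frame, triphone, loglik) streams.

    Triphone labels use the 'left-centre+right' notation.  Intended for
    small hand-editable cases; the HDF5 container is the primary format.
    """
    df = pd.read_csv(path)
    required = {"condition", "frame", "triphone", "loglik"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")

    def parse(label: str) -> TriphoneLabel:
        left, rest = label.split("-", 1)
        centre, right = rest.split("+", 1)
        return TriphoneLabel(left, centre, right)

    conds = sorted(df["condition"].astype(str).unique())
    tris = sorted(df["triphone"].astype(str).unique())
    n_frames = int(df["frame"].max()) + 1
    values = np.zeros((len(conds), n_frames, len(tris)))
    ci = {c: i for i, c in enumerate(conds)}
    ti = {t: i for i, t in enumerate(tris)}
    for row in df.itertuples(index=False):
        values[ci[str(row.condition)], int(row.frame), ti[str(row.triphone)]] = (
            row.loglik
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cs = ConditionSet(conds)
    return LikelihoodStreamSet(
        conditions=cs,
        triphones=tuple(parse(t) for t in tris),
        values=values,
    )


def save_source_epochs(epochs: SourceEpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _write_conditions(f, epochs.conditions)
        f.attrs["t_start_ms"] = epochs.t_start_ms
        f.attrs["sample_ms"] = epochs.sample_ms
        grp = f.create_group("epochs")
        for i, subj in enumerate(epochs.subjects):
            sg = grp.create_group(subj)
            for j, cond in enumerate(epochs.conditions.labels):
                sg.create_dataset(
                    cond, data=epochs.data[i, j].astype(np.float32)
                )


def load_source_epochs(path: str | Path) -> SourceEpochSet:
    with h5py.File(path, "r") as f:
        cs = _read_conditions(f)
        grp = f["epochs"]
        subjects = tuple(grp)
        data = np.stack(
            [
                np.stack([grp[s][c][()] for c in cs.labels])
                for s in subjects
            ]
        ).astype(np.float64)
        t_start = int(f.attrs["t_start_ms"])
    return SourceEpochSet(
        subjects=subjects, conditions=cs, data=data, t_start_ms=t_start
    )


def load_mesh_and_epochs(
    mesh_path: str | Path, epochs_path: str | Path
):
    """Convenience loader pairing a mesh TSV with an epoch container."""
    from ssrsa.brain_states import load_mesh_tsv

    return load_mesh_tsv(mesh_path), load_source_epochs(epochs_path)


def save_null_distributions(
    nulls: Mapping[str, NullDistribution], path: str | Path
) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("null")
        for feat, nd in nulls.items():
            g = root.create_group(feat)
            g.create_dataset("samples", data=nd.samples)
            g.attrs["n_perm"] = nd.n_perm


def load_null_distributions(
    path: str | Path,
) -> dict[str, NullDistribution]:
    with h5py.File(path, "r") as f:
        root = f["null"]
        return {
            feat: NullDistribution(
                feature=feat,
                samples=root[feat]["samples"][()],
                n_perm=int(root[feat].attrs["n_perm"]),
            )
            for feat in root
        }


def feature_maps_to_frame(
    maps: Mapping[str, FeatureFitMap]
) -> pd.DataFrame:
    """Thresholded maps as a tidy table (one row per vertex x feature)."""
    rows = []
    for feat, fmap in maps.items():
        surviving = (
            set(fmap.surviving) if fmap.threshold is not None else set()
        )
        for vertex, fit in fmap.fits.items():
            rows.append(
                {
                    "vertex_id": vertex,
                    "feature": feat,
                    "fit": fit,
                    "threshold": fmap.threshold,
                    "quantile": fmap.quantile,
                    "survives": vertex in surviving,
                }
            )
    return pd.DataFrame(rows)
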