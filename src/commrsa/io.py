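"""Serialization: TSV for tabular records, HDF5 for response arrays.

Layout of a study directory:

    sequences.tsv        observer_id, run_id, trial_index, object_id,
                         is_recurring, onset_s
    graph_edges.tsv      edge list (node_i, node_j)
    graph_nodes.tsv      node_id, community, role
    responses.h5         one dataset /responses/obs{u}/parcel{w} per
                         (observer, parcel), trials x Ndim, plus fitted
                         subspaces under /subspaces
    distances.tsv        pairwise-distance records
    reports/*.tsv        sensitivity, identity and geometry tables

The ingest functions accept the same layout, so externally prepared parcel
responses can be analyzed without code changes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dlda import DiscriminantSubspace
from .graphs import N_OBJECTS, CommunityGraph
from .simulate import ParcelResponseSet
from .walks import TrialSequence

__all__ = [
    "write_sequences",
    "read_sequences",
    "write_graph",
    "read_graph",
    "write_responses",
    "read_responses",
    "write_subspace",
    "read_subspace",
]


def write_sequences(sequences: list[TrialSequence], path) -> None:
    pd.concat([s.to_frame() for s in sequences], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_sequences(path) -> list[TrialSequence]:
    df = pd.read_csv(path, sep="\t")
    return [
        TrialSequence.from_frame(sub)
        for _, sub in df.groupby(["observer_id", "run_id"])
    ]


def write_graph(graph: CommunityGraph, edge_path, node_path) -> None:
    i, j = np.nonzero(np.triu(graph.adjacency))
    pd.DataFrame({"node_i": i, "node_j": j}).to_csv(edge_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "node_id": np.arange(N_OBJECTS),
            "community": graph.community_of,
            "role": graph.role_of,
        }
    ).to_csv(node_path, sep="\t", index=False)


def read_graph(edge_path, node_path, name: str = "modular") -> CommunityGraph:
    edges = pd.read_csv(edge_path, sep="\t")
    nodes = pd.read_csv(node_path, sep="\t").sort_values("node_id")
    A = np.zeros((N_OBJECTS, N_OBJECTS), dtype=bool)
    A[edges["node_i"], edges["node_j"]] = True
    A |= A.T
    return CommunityGraph(
        A,
        nodes["community"].to_numpy(),
        nodes["role"].to_numpy(),
        name=name,
    )


def _rs_key(observer_id: int, parcel_id) -> str:
    return f"responses/obs{observer_id}/parcel{parcel_id}"


def write_responses(response_sets: list[ParcelResponseSet], h5_path) -> None:
    """Write response matrices to HDF5 (metadata goes in sequences.tsv)."""
    with h5py.File(h5_path, "a") as f:
        for rs in response_sets:
            key = _rs_key(rs.observer_id, rs.parcel_id)
            if key in f:
                del f[key]
            d = f.create_dataset(key, data=rs.responses)
            d.attrs["observer_id"] = rs.observer_id
            d.attrs["parcel_id"] = str(rs.parcel_id)


def read_responses(h5_path, sequences_path) -> list[ParcelResponseSet]:
    meta = pd.read_csv(sequences_path, sep="\t")
    out = []
    with h5py.File(h5_path, "r") as f:
        grp = f["responses"]
        for okey in sorted(grp):
            u = int(okey.removeprefix("obs"))
            sub_meta = meta[meta["observer_id"] == u].reset_index(drop=True)
            for pkey in sorted(grp[okey]):
                d = grp[okey][pkey]
                pid = d.attrs["parcel_id"]
                try:
                    pid = int(pid)
                except ValueError:
                    pass
                out.append(
                    ParcelResponseSet(pid, u, d[()], sub_meta.copy())
                )
    return out


def write_subspace(sub: DiscriminantSubspace, h5_path, key: str) -> None:
    with h5py.File(h5_path, "a") as f:
        g_key = f"subspaces/{key}"
        if g_key in f:
            del f[g_key]
        g = f.create_group(g_key)
        g.create_dataset("basis", data=sub.basis)
        g.create_dataset("scaling", data=sub.scaling)
        g.create_dataset("class_means", data=sub.class_means)
        g.create_dataset("classes", data=np.asarray(sub.classes, dtype=int))
        g.create_dataset("offset", data=sub.offset)
        g.attrs["kappa"] = sub.kappa
        g.attrs["fitted_on"] = sub.fitted_on


def read_subspace(h5_path, key: str) -> DiscriminantSubspace:
    with h5py.File(h5_path, "r") as f:
        g = f[f"subspaces/{key}"]
        return DiscriminantSubspace(
            basis=g["basis"][()],
            scaling=g["scaling"][()],
            kappa=int(g.attrs["kappa"]),
            classes=g["classes"][()],
            class_means=g["class_means"][()],
            offset=g["offset"][()],
            fitted_on=str(g.attrs["fitted_on"]),
        )
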