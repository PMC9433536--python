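"""Readers and writers for the package's text formats.

Recordings travel as a wide CSV (one ``t`` column plus one column per
channel, or per channel x wavelength for optical-density data) next to a
JSON sidecar carrying the sampling rate, signal kind, wavelengths, event
timing and the channel-to-region map.  Trajectories are long CSVs; artifact
masks are half-open interval TSVs; PLV matrices are square TSVs with channel
headers; adjacency goes out as an edge list and optionally GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityNetwork
from .kinematics import TrajectoryTrace
from .preprocess import ArtifactMask
from .recording import Event, HemoglobinSeries, NirsRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_hemoglobin",
    "read_hemoglobin",
    "write_trajectories",
    "read_trajectories",
    "write_artifact_mask",
    "write_plv_matrix",
    "read_plv_matrix",
    "write_adjacency",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def _events_to_json(events: list[Event]) -> list[dict]:
    return [dict(onset=e.onset, duration=e.duration, condition=e.condition) for e in events]


def _events_from_json(items: list[dict]) -> list[Event]:
    return [Event(onset=i["onset"], duration=i["duration"], condition=i["condition"]) for i in items]


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def write_recording(rec: NirsRecording, csv_path: str | Path) -> Path:
    """Write a recording as wide CSV + JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    cols: dict[str, np.ndarray] = {"t": rec.t}
    if rec.signal_kind == "optical_density":
        for k in range(rec.n_channels):
            for w, wl in enumerate(rec.wavelengths):
                cols[f"ch{k:02d}_{wl:g}nm"] = rec.channels[:, k, w]
    else:
        for k in range(rec.n_channels):
            cols[f"ch{k:02d}"] = rec.channels[:, k]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = dict(
        signal_kind=rec.signal_kind,
        rate_hz=rec.rate,
        wavelengths_nm=list(rec.wavelengths) if rec.wavelengths else None,
        channel_regions=list(rec.channel_regions),
        events=_events_to_json(rec.events),
    )
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(csv_path: str | Path) -> NirsRecording:
    csv_path = Path(csv_path)
    side = json.loads(_sidecar_path(csv_path).read_text())
    if side.get("channel_regions") is None:
        raise ValueError(f"{csv_path}: sidecar lacks the channel_regions map")
    df = pd.read_csv(csv_path)
    _require_columns(df, ["t"], csv_path)
    regions = side["channel_regions"]
    n_ch = len(regions)
    kind = side["signal_kind"]
    if kind == "optical_density":
        wls = side["wavelengths_nm"]
        names = [f"ch{k:02d}_{wl:g}nm" for k in range(n_ch) for wl in wls]
        _require_columns(df, names, csv_path)
        data = df[names].to_numpy().reshape(len(df), n_ch, len(wls))
        wavelengths = tuple(float(w) for w in wls)
    else:
        names = [f"ch{k:02d}" for k in range(n_ch)]
        _require_columns(df, names, csv_path)
        data = df[names].to_numpy()
        wavelengths = None
    return NirsRecording(
        t=df["t"].to_numpy(),
        channels=data,
        signal_kind=kind,
        channel_regions=regions,
        events=_events_from_json(side["events"]),
        rate=side["rate_hz"],
        wavelengths=wavelengths,
    )


def write_hemoglobin(h: HemoglobinSeries, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    cols: dict[str, np.ndarray] = {"t": h.t}
    for k in range(h.n_channels):
        cols[f"ch{k:02d}_hbo"] = h.dhbo[:, k]
        cols[f"ch{k:02d}_hbr"] = h.dhbr[:, k]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = dict(
        rate_hz=h.rate,
        channel_regions=list(h.channel_regions),
        events=_events_to_json(h.events),
    )
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_hemoglobin(csv_path: str | Path) -> HemoglobinSeries:
    csv_path = Path(csv_path)
    side = json.loads(_sidecar_path(csv_path).read_text())
    df = pd.read_csv(csv_path)
    regions = side["channel_regions"]
    n_ch = len(regions)
    hbo_names = [f"ch{k:02d}_hbo" for k in range(n_ch)]
    hbr_names = [f"ch{k:02d}_hbr" for k in range(n_ch)]
    _require_columns(df, ["t"] + hbo_names + hbr_names, csv_path)
    return HemoglobinSeries(
        t=df["t"].to_numpy(),
        dhbo=df[hbo_names].to_numpy(),
        dhbr=df[hbr_names].to_numpy(),
        rate=side["rate_hz"],
        channel_regions=regions,
        events=_events_from_json(side["events"]),
    )


_TRAJ_COLS = ["subject", "condition", "trial", "hand", "t", "x", "y",
              "center_x", "center_y", "guide_radius", "guide_angular_velocity"]


def write_trajectories(traces: list[TrajectoryTrace], csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame(dict(
            subject=tr.subject, condition=tr.condition, trial=tr.trial, hand=tr.hand,
            t=tr.t, x=tr.x, y=tr.y,
            center_x=tr.center[0], center_y=tr.center[1],
            guide_radius=tr.guide_radius,
            guide_angular_velocity=tr.guide_angular_velocity,
        )))
    pd.concat(frames, ignore_index=True)[_TRAJ_COLS].to_csv(csv_path, index=False)
    return csv_path


def read_trajectories(csv_path: str | Path) -> list[TrajectoryTrace]:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    _require_columns(df, _TRAJ_COLS, csv_path)
    traces = []
    for (subj, cond, trial, hand), grp in df.groupby(
            ["subject", "condition", "trial", "hand"], sort=False):
        grp = grp.sort_values("t")
        traces.append(TrajectoryTrace(
            t=grp["t"].to_numpy(), x=grp["x"].to_numpy(), y=grp["y"].to_numpy(),
            hand=hand, condition=cond,
            center=(grp["center_x"].iloc[0], grp["center_y"].iloc[0]),
            guide_radius=grp["guide_radius"].iloc[0],
            guide_angular_velocity=grp["guide_angular_velocity"].iloc[0],
            subject=subj, trial=int(trial),
        ))
    return traces


def write_artifact_mask(mask: ArtifactMask, tsv_path: str | Path) -> Path:
    """Half-open flagged intervals as TSV: channel, start_sample, end_sample."""
    tsv_path = Path(tsv_path)
    rows = [dict(channel=ch, start_sample=a, end_sample=b)
            for ch, segs in sorted(mask.segments.items()) for a, b in segs]
    pd.DataFrame(rows, columns=["channel", "start_sample", "end_sample"]).to_csv(
        tsv_path, sep="\t", index=False)
    return tsv_path


def write_plv_matrix(net: ConnectivityNetwork, tsv_path: str | Path) -> Path:
    tsv_path = Path(tsv_path)
    names = [f"ch{k:02d}" for k in range(net.n_channels)]
    pd.DataFrame(net.plv, index=names, columns=names).to_csv(tsv_path, sep="\t")
    return tsv_path


def read_plv_matrix(tsv_path: str | Path) -> np.ndarray:
    return pd.read_csv(Path(tsv_path), sep="\t", index_col=0).to_numpy()


def write_adjacency(net: ConnectivityNetwork, tsv_path: str | Path,
                    graphml_path: str | Path | None = None) -> Path:
    """Edge list TSV (node_i, node_j, plv); optional GraphML export."""
    tsv_path = Path(tsv_path)
    if net.adjacency is None:
        raise ValueError("network has not been thresholded")
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    pd.DataFrame(dict(node_i=ii, node_j=jj, plv=net.plv[ii, jj])).to_csv(
        tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        G = nx.from_numpy_array(net.adjacency.astype(int))
        for u, v in G.edges:
            G[u][v]["plv"] = float(net.plv[u, v])
        nx.write_graphml(G, graphml_path)
    return tsv_path
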