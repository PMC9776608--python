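"""File formats: model JSON/YAML, GMT gene sets, DE/RNK tables, trajectories.

Gene identifiers are treated as opaque, case-sensitive strings throughout
— no symbol/ID mapping layer is provided.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enrichment import GeneSet, RankedList, _validate_p
from .network import NetworkModel
from .simulate import Trajectory

__all__ = [
    "load_model_file",
    "save_model_file",
    "bundled_model_path",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "write_de_table",
    "read_rnk",
    "write_rnk",
    "write_trajectory",
    "read_trajectory",
]

logger = logging.getLogger("prostnet")

MODEL_KEYS = {"labels", "J", "d", "A"}


def bundled_model_path() -> Path:
    """Path of the packaged six-node crosstalk model definition."""
    return Path(resources.files("prostnet") / "data" / "ar_nfkb_model.json")


def load_model_file(path: str | Path) -> NetworkModel:
    """Load a :class:`NetworkModel` from JSON or YAML.

    The file must contain exactly the keys ``labels``, ``J``, ``d`` and
    ``A`` (A as a row-major list of rows).  Validation errors name the
    offending field.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: model file must contain a mapping")
    unknown = set(raw) - MODEL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    missing = MODEL_KEYS - set(raw)
    if missing:
        raise ValueError(f"{path}: missing keys {sorted(missing)}")
    try:
        return NetworkModel(
            labels=tuple(raw["labels"]), J=raw["J"], d=raw["d"], A=raw["A"]
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: invalid model: {exc}") from exc


def save_model_file(model: NetworkModel, path: str | Path) -> None:
    """Write a model as JSON (or YAML if the suffix says so)."""
    payload = {
        "labels": list(model.labels),
        "J": model.J.tolist(),
        "d": model.d.tolist(),
        "A": model.A.tolist(),
    }
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a set are dropped with a logged warning;
    malformed lines raise with their line number.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: expected at least 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, desc, *members = fields
        members = [m for m in members if m]
        unique = set(members)
        if len(unique) != len(members):
            logger.warning(
                "%s:%d: set %r has duplicate members; deduplicated", path, lineno, name
            )
        sets.append(GeneSet(name=name, description=desc, members=frozenset(unique)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT, members sorted for reproducible output."""
    lines = [
        "\t".join([s.name, s.description, *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DE tables and RNK ranked lists


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV DE table ``gene<TAB>log2fc<TAB>pvalue[<TAB>adj_p]``.

    Rejects duplicate genes, missing values and p-values outside (0, 1],
    reporting the offending rows.
    """
    table = pd.read_csv(path, sep="\t")
    required = ["gene", "log2fc", "pvalue"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    numeric = ["log2fc", "pvalue"] + (["adj_p"] if "adj_p" in table.columns else [])
    bad = table[table[numeric].isna().any(axis=1)]
    if not bad.empty:
        rows = (bad.index + 2).tolist()[:10]  # +2: header plus 1-based
        raise ValueError(f"{path}: missing/non-numeric values at rows {rows}")
    dup = table.loc[table["gene"].duplicated(), "gene"]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene rows: {dup.unique()[:10].tolist()}")
    p = table["pvalue"].to_numpy(dtype=float)
    out = np.flatnonzero((p <= 0) | (p > 1))
    if out.size:
        rows = (out + 2).tolist()[:10]
        raise ValueError(f"{path}: p-values outside (0, 1] at rows {rows}")
    table["gene"] = table["gene"].astype(str)
    return table


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table as TSV with 12 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_rnk(path: str | Path) -> RankedList:
    """Read a two-column RNK file (gene, score), already rank-ordered."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return RankedList(
        genes=tuple(df["gene"].astype(str)), stats=df["score"].to_numpy(float)
    )


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    lines = [f"{g}\t{s:.12g}" for g, s in zip(ranked.genes, ranked.stats)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectories


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV plus a JSON metadata sidecar.

    The CSV has header ``time,<label1>,...``; the sidecar ``<path>.meta.json``
    records dt, seed and the applied events.
    """
    path = Path(path)
    df = pd.DataFrame(traj.states, columns=list(traj.labels))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "dt": traj.dt,
        "seed": traj.seed,
        "events_applied": [
            {
                "time": ev.time,
                "node": ev.node,
                "old_value": ev.old_value,
                "new_value": ev.new_value,
            }
            for ev in traj.events_applied
        ],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1) + "\n"
    )


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    dt, seed = float("nan"), None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        dt, seed = meta.get("dt", float("nan")), meta.get("seed")
    return Trajectory(
        times=df["time"].to_numpy(float),
        states=df.iloc[:, 1:].to_numpy(float),
        labels=tuple(df.columns[1:]),
        seed=seed,
        dt=dt,
    )
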