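"""Reading and writing of the on-disk cohort representations.

Everything is plain delimited text (TSV by default, CSV accepted):
square connectome matrices with a header row of node ids, node x TR
timeseries tables, two-column node->network label tables, and a subjects
table. Validation is strict and total: malformed input raises a typed
:class:`ValidationError`, never a silent pass-through.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: symmetry tolerance for connectome matrices; larger asymmetry is an error
SYMMETRY_TOL = 1e-8

DEFAULT_GROUPS = ("control", "athlete")


class ValidationError(ValueError):
    """Raised when an on-disk table or in-memory object violates a contract."""


@dataclass(frozen=True)
class Connectome:
    """Weighted, symmetric structural brain network.

    Edge weights are unitless normalized streamline counts (tract count over
    median fiber length). ``network_of`` assigns every node to an intrinsic
    connectivity network.
    """

    node_ids: tuple
    weights: np.ndarray
    network_of: dict

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = len(self.node_ids)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"non-square weight matrix {w.shape}")
        if w.shape[0] != n:
            raise ValidationError(
                f"{n} node ids but {w.shape[0]}x{w.shape[1]} matrix"
            )
        if len(set(self.node_ids)) != n:
            raise ValidationError("duplicate node ids")
        if not np.isfinite(w).all():
            raise ValidationError("non-finite connectome weights")
        if (w < 0).any():
            raise ValidationError("negative connectome weights")
        asym = np.abs(w - w.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"asymmetry {asym:.3g} exceeds {SYMMETRY_TOL}")
        if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
            raise ValidationError("nonzero diagonal")
        missing = [i for i in self.node_ids if i not in self.network_of]
        if missing:
            raise ValidationError(f"nodes without network label: {missing[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def networks(self) -> tuple:
        """Distinct network names in first-appearance (node) order."""
        seen = {}
        for i in self.node_ids:
            seen.setdefault(self.network_of[i], None)
        return tuple(seen)


@dataclass(frozen=True)
class ParcellatedBold:
    """Area-mean BOLD timeseries (nodes x TRs), paired with a connectome."""

    node_ids: tuple
    data: np.ndarray
    tr_seconds: float = 3.0

    def __post_init__(self):
        x = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", x)
        if x.ndim != 2 or x.shape[0] != len(self.node_ids):
            raise ValidationError(
                f"timeseries shape {x.shape} does not match {len(self.node_ids)} nodes"
            )
        if x.shape[1] < 2:
            raise ValidationError("TRs >= 2 required")
        if not np.isfinite(x).all():
            bad = np.argwhere(~np.isfinite(x))[0]
            raise ValidationError(f"missing value at (node {bad[0]}, TR {bad[1]})")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicate node ids")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age_years: float
    group: str
    mean_fd_mm: float

    def __post_init__(self):
        if not (0 < self.age_years < 150):
            raise ValidationError(f"age {self.age_years} outside (0, 150)")
        if not np.isfinite(self.mean_fd_mm) or self.mean_fd_mm < 0:
            raise ValidationError(f"bad mean FD {self.mean_fd_mm}")


def _read_table(path, **kw) -> pd.DataFrame:
    # sniff tab vs comma from the header; the C engine with round_trip
    # parsing keeps float round-trips exact
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        return pd.read_csv(path, sep=sep, float_precision="round_trip", **kw)
    except (pd.errors.EmptyDataError, StopIteration) as e:
        raise ValidationError(f"{path}: empty file") from e


def read_labels(path) -> dict:
    """Two-column node_id -> network table; order defines canonical node order."""
    df = _read_table(path)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected 2 columns, got {df.shape[1]}")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate node ids")
    return dict(zip(ids, df.iloc[:, 1].astype(str)))


def read_connectome(path, labels_path) -> Connectome:
    """Read a square weighted adjacency table and its network labels.

    Node order is canonicalized to the labels file. Asymmetry up to
    ``SYMMETRY_TOL`` is symmetrized by averaging; a tiny nonzero diagonal is
    zeroed with a logged warning.
    """
    network_of = read_labels(labels_path)
    df = _read_table(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: non-square matrix {df.shape}")
    ids = [str(c) for c in df.columns]
    if set(ids) != set(network_of):
        raise ValidationError(f"{path}: node ids do not match labels file")
    order = list(network_of)
    df.index = [str(i) for i in df.index]
    df = df.loc[order, order]
    w = df.to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValidationError(f"{path}: missing values in matrix")
    asym = np.abs(w - w.T).max(initial=0.0)
    if asym > SYMMETRY_TOL:
        raise ValidationError(f"{path}: asymmetry {asym:.3g} > {SYMMETRY_TOL}")
    w = 0.5 * (w + w.T)
    if np.abs(np.diag(w)).max(initial=0.0) > 0:
        logger.warning("%s: nonzero diagonal zeroed", path)
        np.fill_diagonal(w, 0.0)
    return Connectome(tuple(order), w, network_of)


def read_timeseries(path, demean: bool = True, tr_seconds: float = 3.0) -> ParcellatedBold:
    """Read a nodes x TRs table; first column holds node ids.

    Each node's temporal mean is removed when ``demean`` is set (default),
    mirroring standard BOLD preprocessing.
    """
    df = _read_table(path, index_col=0)
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate node ids")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: TRs >= 2 required")
    x = df.to_numpy(dtype=float)
    if np.isnan(x).any():
        node, tr = np.argwhere(np.isnan(x))[0]
        raise ValidationError(f"{path}: missing value at (node {ids[node]}, TR {tr})")
    if demean:
        x = x - x.mean(axis=1, keepdims=True)
    return ParcellatedBold(tuple(ids), x, tr_seconds)


def read_subjects(path, groups: Sequence[str] = DEFAULT_GROUPS) -> list:
    """Read the subjects table (subject_id, age_years, group, mean_fd_mm)."""
    df = _read_table(path)
    required = {"subject_id", "age_years", "group", "mean_fd_mm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {required - set(df.columns)}")
    if df.empty:
        raise ValidationError(f"{path}: no subjects")
    records = []
    for _, row in df.iterrows():
        g = str(row["group"])
        if g not in groups:
            raise ValidationError(f"{path}: unknown group {g!r} (expected {groups})")
        try:
            age = float(row["age_years"])
            fd = float(row["mean_fd_mm"])
        except (TypeError, ValueError) as e:
            raise ValidationError(f"{path}: non-numeric age/FD for {row['subject_id']}") from e
        records.append(SubjectRecord(str(row["subject_id"]), age, g, fd))
    if len({r.subject_id for r in records}) != len(records):
        raise ValidationError(f"{path}: duplicate subject ids")
    return records


# ---------------------------------------------------------------------------
# writers

def write_connectome(conn: Connectome, path) -> None:
    df = pd.DataFrame(conn.weights, index=list(conn.node_ids), columns=list(conn.node_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_timeseries(bold: ParcellatedBold, path) -> None:
    df = pd.DataFrame(
        bold.data,
        index=list(bold.node_ids),
        columns=[f"tr{t}" for t in range(bold.n_trs)],
    )
    df.index.name = "node_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_labels(network_of: Mapping, path) -> None:
    pd.DataFrame(
        {"node_id": list(network_of), "network": [network_of[i] for i in network_of]}
    ).to_csv(path, sep="\t", index=False)


def write_subjects(subjects: Sequence[SubjectRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in subjects]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def write_results(result, outdir, *, network_of=None, config=None, seed=None,
                  version: str | None = None) -> dict:
    """Write PLS or regression results as TSV files plus a JSON run manifest.

    ``result`` is either a :class:`~neurocouple.pls_brain_age.PlsResult` or a
    regression :class:`pandas.DataFrame`. Returns the manifest dict.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise ValidationError(f"unwritable output directory {outdir}: {e}") from e

    files = []

    def _emit(df: pd.DataFrame, name: str):
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        files.append(name)

    if isinstance(result, pd.DataFrame):
        _emit(result, "regression.tsv")
    else:  # PlsResult
        node_ids = list(result.node_ids)
        nets = [network_of.get(i, "") for i in node_ids] if network_of else [""] * len(node_ids)
        for k in range(result.n_lv):
            _emit(
                pd.DataFrame(
                    {
                        "node_id": node_ids,
                        "network": nets,
                        "salience": result.brain_saliences[:, k],
                        "bsr": result.bsr[:, k],
                        "ci_low": result.ci_low[:, k],
                        "ci_high": result.ci_high[:, k],
                    }
                ),
                f"lv{k + 1}_areas.tsv",
            )
        _emit(
            pd.DataFrame(
                {
                    "lv": np.arange(1, result.n_lv + 1),
                    "singular_value": result.singular_values,
                    "perm_p": result.perm_p,
                    "perm_p_display": [
                        f"<{1.0 / result.n_perm:g}" if p == 0 else f"{p:g}"
                        for p in result.perm_p
                    ],
                }
            ),
            "latent_variables.tsv",
        )
        if result.network_summaries is not None:
            rows = []
            for k, summ in enumerate(result.network_summaries):
                for net in sorted(set(list(summ.positive_mean) + list(summ.negative_mean)
                                      + list(summ.counts))):
                    rows.append(
                        {
                            "lv": k + 1,
                            "network": net,
                            "positive_mean_bsr": summ.positive_mean.get(net, np.nan),
                            "negative_mean_bsr": summ.negative_mean.get(net, np.nan),
                            "n_areas": summ.counts.get(net, 0),
                        }
                    )
            _emit(pd.DataFrame(rows), "network_summary.tsv")

    from . import __version__

    manifest = {
        "files": files,
        "config": config,
        "seed": seed,
        "version": version or __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
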