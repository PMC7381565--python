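"""Plain-text table readers and writers.

Community tables are TSV with sites as rows and genera as columns.
Environment tables carry a second header row assigning each variable to a
predictor set.  Site coordinates are CSV (site, lon, lat).  All writers
round-trip exactly (floats serialized with ``repr``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import PREDICTOR_SETS, CommunityMatrix, DistanceMatrix, PredictorTable

__all__ = [
    "read_community",
    "write_community",
    "read_env",
    "write_env",
    "read_sites",
    "write_sites",
    "read_distance",
    "write_distance",
]


def _fmt(v: float) -> str:
    return repr(int(v)) if float(v).is_integer() else repr(float(v))


def write_community(cm: CommunityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(cm.genera) + "\n")
        for site, row in zip(cm.sites, cm.abundance):
            fh.write(site + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_community(path) -> CommunityMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate genus column(s) in header: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValueError(f"non-numeric abundance in columns {list(bad)}")
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative count at site {df.index[i]!r}, genus {df.columns[j]!r}"
        )
    return CommunityMatrix.from_dataframe(df)


def write_env(env: PredictorTable, path) -> None:
    cols = list(env.values.columns)
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(cols) + "\n")
        fh.write("set\t" + "\t".join(env.set_labels[c] for c in cols) + "\n")
        for site in env.sites:
            row = env.values.loc[site]
            fh.write(site + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_env(path) -> PredictorTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        set_row = fh.readline().rstrip("\n").split("\t")
        body = pd.read_csv(fh, sep="\t", header=None, names=header, index_col=0,
                        float_precision="round_trip")
    variables = header[1:]
    labels = dict(zip(variables, set_row[1:]))
    for var, lab in labels.items():
        if lab not in PREDICTOR_SETS:
            raise ValueError(f"variable {var!r} has unknown set label {lab!r}")
    arr = body.to_numpy(dtype=float)
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"missing value at site {body.index[i]!r}, variable {variables[j]!r}"
        )
    return PredictorTable(list(map(str, body.index)), body.astype(float), labels)


def write_sites(labels, coords, path) -> None:
    with open(path, "w") as fh:
        fh.write("site,lon,lat\n")
        for lab, (lon, lat) in zip(labels, np.asarray(coords, float)):
            fh.write(f"{lab},{float(lon)!r},{float(lat)!r}\n")


def read_sites(path):
    """Returns (labels, coords) with coords an (n, 2) array of (lon, lat)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return list(df.iloc[:, 0].astype(str)), df.iloc[:, 1:3].to_numpy(dtype=float)


def write_distance(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(dm.labels) + "\n")
        for lab, row in zip(dm.labels, dm.d):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_distance(path, metric: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return DistanceMatrix(list(map(str, df.index)), df.to_numpy(dtype=float), metric=metric)
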