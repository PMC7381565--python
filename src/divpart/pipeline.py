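"""One-call driver reproducing the full analysis graph.

``run_all`` reads a community table, an environment table and site
coordinates, then executes: diversity metrics -> elastic-net variation
partitioning with permutation tests (richness and Shannon) and a Moran's I
residual check -> Jaccard / Bray-Curtis dissimilarity -> NMDS + envfit +
Mantel-vs-space -> distance-based variation partitioning.  Every output is
a plain-text table or JSON record, and a ``RunRecord`` captures the
configuration, per-stage seeds and library versions needed to reproduce the
run bit-for-bit.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import diversity as div
from .elastic_net import fit_en_cv, standardize
from .io import read_community, read_env, read_sites, write_distance
from .varpart import morans_i, permutation_test_fractions

__all__ = ["RunConfig", "RunRecord", "run_all"]

_STAGES = ("diversity", "varpart_richness", "varpart_shannon", "composition")


@dataclass
class RunConfig:
    """Paths and analysis switches for one end-to-end run."""

    community: str
    env: str
    sites: str
    out_dir: str
    responses: tuple[str, ...] = ("richness", "shannon")
    indices: tuple[str, ...] = ("jaccard", "braycurtis")
    repeats: int = 100
    repeats_null: int = 10
    n_perm: int = 999
    folds: int = 5
    alpha_grid: list | None = None
    n_lambda: int = 50
    nmds_k: int = 2
    nmds_starts: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.responses = tuple(cfg.responses)
        cfg.indices = tuple(cfg.indices)
        return cfg

    def validate(self) -> None:
        for name in ("community", "env", "sites"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        for r in self.responses:
            if r not in ("richness", "shannon"):
                raise ValueError(f"unknown response {r!r}")
        for ix in self.indices:
            if ix not in ("jaccard", "braycurtis"):
                raise ValueError(f"unknown dissimilarity index {ix!r}")


@dataclass
class RunRecord:
    config: dict
    stage_seeds: dict[str, int]
    versions: dict[str, str]
    wall_time_s: float = 0.0
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    kids = ss.spawn(8)
    names = ["varpart_richness", "varpart_shannon", "moran", "nmds",
             "envfit", "mantel", "dbpart", "spare"]
    return {n: int(k.generate_state(1)[0] % 2**31) for n, k in zip(names, kids)}


def _partition_table(res) -> pd.DataFrame:
    rows = []
    for key in list(res.fractions) + [f"total_{s}" for s in res.totals]:
        value = res.fractions.get(key, res.totals.get(key.removeprefix("total_")))
        rows.append(
            {
                "fraction": key,
                "value": value,
                "p": None if res.pvalues is None else res.pvalues[key],
                "significant": None if res.significant is None else res.significant[key],
            }
        )
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> RunRecord:
    """Execute every analysis stage; returns the reproducibility record."""
    t0 = time.perf_counter()
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    record = RunRecord(
        config=asdict(cfg),
        stage_seeds=seeds,
        versions={
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "divpart": "0.1.0",
        },
    )

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        record.outputs.append(name)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        community = read_community(cfg.community)
        env = read_env(cfg.env)
        labels, coords = read_sites(cfg.sites)
        if labels != list(community.sites) or labels != list(env.sites):
            raise ValueError("site order differs between community, environment and sites files")

        # --- diversity responses
        responses = {
            "richness": div.richness(community).astype(float),
            "shannon": div.shannon(community),
        }
        save(
            pd.DataFrame(responses, index=community.sites).rename_axis("site"),
            "diversity.tsv",
        )

        # --- elastic-net variation partitioning per response
        for resp in cfg.responses:
            y = responses[resp]
            res = permutation_test_fractions(
                y, env, n_perm=cfg.n_perm, repeats_null=cfg.repeats_null,
                seed=seeds[f"varpart_{resp}"], repeats=cfg.repeats, folds=cfg.folds,
                alpha_grid=cfg.alpha_grid, n_lambda=cfg.n_lambda,
            )
            save(_partition_table(res), f"varpart_{resp}.tsv", index=False)
            # residual spatial-autocorrelation check on the full (CSH) model
            fit = fit_en_cv(
                y, env.values.to_numpy(float), folds=cfg.folds,
                alpha_grid=cfg.alpha_grid, seed=seeds["moran"], n_lambda=cfg.n_lambda,
            )
            resid = y - fit.predict(standardize(env.values.to_numpy(float)))
            moran = morans_i(resid, coords=coords, n_perm=cfg.n_perm, seed=seeds["moran"])
            with open(out / f"moran_{resp}.json", "w") as fh:
                json.dump(
                    {"I": moran.I, "expected": moran.expected, "p": moran.p,
                     "n_permutations": moran.n_permutations},
                    fh, indent=1,
                )
            record.outputs.append(f"moran_{resp}.json")

        # --- composition analyses per dissimilarity index
        space = comp.geographic_distance(coords, labels)
        for index in cfg.indices:
            d = (div.jaccard_matrix if index == "jaccard" else div.braycurtis_matrix)(community)
            write_distance(d, out / f"dist_{index}.tsv")
            record.outputs.append(f"dist_{index}.tsv")

            ordn = comp.nmds(d, k=cfg.nmds_k, n_starts=cfg.nmds_starts, seed=seeds["nmds"])
            scores = pd.DataFrame(
                ordn.scores, index=labels,
                columns=[f"NMDS{i + 1}" for i in range(cfg.nmds_k)],
            ).rename_axis("site")
            scores["stress"] = ordn.stress
            save(scores, f"nmds_{index}.tsv")

            fitted = comp.envfit(ordn, env, n_perm=cfg.n_perm, seed=seeds["envfit"])
            save(fitted, f"envfit_{index}.tsv")

            mres = comp.mantel(d, space, n_perm=cfg.n_perm, seed=seeds["mantel"])
            with open(out / f"mantel_{index}.json", "w") as fh:
                json.dump({"r": mres.r, "p": mres.p, "n_permutations": mres.n_permutations},
                          fh, indent=1)
            record.outputs.append(f"mantel_{index}.json")

            dbres = comp.db_varpart(d, env, n_perm=cfg.n_perm, seed=seeds["dbpart"])
            save(_partition_table(dbres), f"db_varpart_{index}.tsv", index=False)

        record.warnings = [str(w.message) for w in caught]

    record.wall_time_s = time.perf_counter() - t0
    with open(out / "run_record.json", "w") as fh:
        json.dump(asdict(record), fh, indent=1)
    return record
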