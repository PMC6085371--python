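"""CSV readers/writers and validation against the study-selection criteria.

Dialect: comma-separated UTF-8 with a header row, one observation per row:

    study_id, series, time_d, cum_co2_mgC_per_g, sd,
    soc_mgC_per_g, added_c_mgC_per_g, nc_category, n_replicates, source

``series`` is one of old_control / old_treatment / new_treatment; times are
days since the substrate addition (t = 0).  Study-level metadata is repeated
on every row so a single file is self-contained.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import SERIES_NAMES, ObservationSet
from .synthetic import SyntheticStudy

__all__ = ["CriteriaError", "load_study", "save_study", "load_collection",
           "save_collection"]

_COLUMNS = ["study_id", "series", "time_d", "cum_co2_mgC_per_g", "sd",
            "soc_mgC_per_g", "added_c_mgC_per_g", "nc_category",
            "n_replicates", "source"]


class CriteriaError(ValueError):
    """The study fails one or more of the data-selection criteria; the
    message lists every violation."""


def save_study(obs: ObservationSet, path, source: str = "") -> None:
    rows = []
    for nm in SERIES_NAMES:
        if nm not in obs.series:
            continue
        for t, z, sd in obs.series[nm]:
            rows.append({
                "study_id": obs.study_id, "series": nm, "time_d": t,
                "cum_co2_mgC_per_g": z, "sd": sd,
                "soc_mgC_per_g": obs.soc, "added_c_mgC_per_g": obs.added_c,
                "nc_category": obs.nc_category,
                "n_replicates": obs.n_replicates, "source": source,
            })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def load_study(path) -> ObservationSet:
    """Read one study file and validate it; raises :class:`CriteriaError`
    listing every violated selection criterion."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - {"source"} - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path.name}: no observations")
    sids = df["study_id"].unique()
    if len(sids) != 1:
        raise ValueError(f"{path.name}: expected one study per file, "
                         f"found {list(sids)}")
    meta = df.iloc[0]
    series = {}
    for nm, grp in df.groupby("series"):
        if nm not in SERIES_NAMES:
            raise ValueError(f"{path.name}: unknown series {nm!r}")
        series[nm] = grp[["time_d", "cum_co2_mgC_per_g", "sd"]].to_numpy(float)
    obs = ObservationSet(
        study_id=str(meta["study_id"]), soc=float(meta["soc_mgC_per_g"]),
        added_c=float(meta["added_c_mgC_per_g"]),
        nc_category=str(meta["nc_category"]),
        n_replicates=int(meta["n_replicates"]), series=series)
    problems = obs.criteria_violations()
    if problems:
        raise CriteriaError(f"{path.name} rejected: " + "; ".join(problems))
    return obs


def save_collection(studies, directory, manifest_extra: dict | None = None):
    """Write a list of ObservationSet (or SyntheticStudy) to one CSV per
    study plus a manifest.json; returns the manifest dict."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    man: dict = {"studies": {}}
    if manifest_extra:
        man.update(manifest_extra)
    for s in studies:
        obs = s.observations if isinstance(s, SyntheticStudy) else s
        save_study(obs, directory / f"{obs.study_id}.csv")
        entry = {"soc": obs.soc, "added_c": obs.added_c,
                 "nc_category": obs.nc_category,
                 "n_replicates": obs.n_replicates}
        if isinstance(s, SyntheticStudy):
            entry["true_params"] = s.true_params
        man["studies"][obs.study_id] = entry
    with open(directory / "manifest.json", "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True)
    return man


def load_collection(directory) -> list[ObservationSet]:
    """Read every study CSV in a directory (sorted by filename)."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no study CSVs under {directory}")
    return [load_study(p) for p in paths]
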