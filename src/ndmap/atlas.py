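"""Parcellation atlas: region metadata, homologue pairing, lobe strata.

The atlas anchors every other stage: canonical region order, ipsi/contra
relabelling relative to a patient's seizure focus, lobe-wise aggregation,
and the spherical coordinates used by spin permutation nulls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right", "midline")
LOBES = ("frontal", "parietal", "temporal", "occipital", "insula", "subcortex")

_COLUMNS = [
    "region_id", "name", "hemisphere", "lobe", "is_cortical", "homologue_id",
    "cx", "cy", "cz", "sx", "sy", "sz",
]


class Atlas:
    """Region table with homologue pairing and geometry.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per region with columns ``region_id, name, hemisphere, lobe,
        is_cortical, homologue_id, cx, cy, cz`` and, for cortical regions,
        unit-sphere coordinates ``sx, sy, sz``.  Row order defines the
        canonical region order used by every matrix in the pipeline.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.reset_index(drop=True).copy()
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        self.table = table
        self._validate()
        self._pos = {int(r): i for i, r in enumerate(table["region_id"])}

    # -- invariants -------------------------------------------------------
    def _validate(self) -> None:
        t = self.table
        ids = t["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        bad_hemi = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {bad_hemi}")
        bad_lobe = set(t["lobe"]) - set(LOBES)
        if bad_lobe:
            raise ValueError(f"unknown lobe labels: {bad_lobe}")
        sub = t["lobe"] == "subcortex"
        if not (sub == ~t["is_cortical"].astype(bool)).all():
            raise ValueError("lobe=subcortex must coincide with is_cortical=False")
        idset = set(int(i) for i in ids)
        for _, row in t.iterrows():
            h = int(row["homologue_id"])
            if h not in idset:
                raise ValueError(f"homologue id {h} of region {row['region_id']} not in atlas")
            twin = t.loc[t["region_id"] == h].iloc[0]
            if int(twin["homologue_id"]) != int(row["region_id"]):
                raise ValueError("homologue pairing is not an involution")
            if row["hemisphere"] == "midline":
                if h != int(row["region_id"]):
                    raise ValueError("midline regions must be self-paired")
            elif h != int(row["region_id"]):
                pair = {row["hemisphere"], twin["hemisphere"]}
                if pair != {"left", "right"}:
                    raise ValueError("homologue pairs must have opposite hemispheres")
        cort = t[t["is_cortical"].astype(bool)]
        sph = cort[["sx", "sy", "sz"]].to_numpy(float)
        if np.isnan(sph).any():
            raise ValueError("cortical regions need sphere coordinates")
        norms = np.linalg.norm(sph, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("sphere coordinates must have unit norm")

    # -- accessors --------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy(int)

    def index_of(self, region_id: int) -> int:
        return self._pos[int(region_id)]

    @property
    def cortical_mask(self) -> np.ndarray:
        return self.table["is_cortical"].to_numpy(bool)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["cx", "cy", "cz"]].to_numpy(float)

    @property
    def sphere_coords(self) -> np.ndarray:
        """Unit-sphere coordinates; NaN rows for subcortical regions."""
        return self.table[["sx", "sy", "sz"]].to_numpy(float)

    def hemisphere_mask(self, hemi: str) -> np.ndarray:
        return (self.table["hemisphere"] == hemi).to_numpy()

    def homologue_index(self) -> np.ndarray:
        """Positional index of each region's contralateral twin."""
        return np.array([self._pos[int(h)] for h in self.table["homologue_id"]])

    def swap_permutation(self) -> np.ndarray:
        """Column permutation exchanging left/right homologues (midline fixed)."""
        return self.homologue_index()

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "Atlas":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Subject table
# ---------------------------------------------------------------------------

GROUPS = ("HC", "TLE", "FCD")

SUBJECT_COLUMNS = [
    "subject_id", "group", "site", "age", "sex", "focus", "hs_status",
    "onset_age", "duration", "n_asm", "fbtcs", "engel_seizure_free", "mean_fd",
]


def validate_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Check subject-table invariants and return a clean copy.

    ``sex`` is coded 0=male, 1=female.  ``focus`` must be ``none`` exactly
    for healthy controls.
    """
    t = subjects.reset_index(drop=True).copy()
    missing = [c for c in ("subject_id", "group", "site", "age", "sex", "focus") if c not in t.columns]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    bad = set(t["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    hc = t["group"] == "HC"
    if not (t.loc[hc, "focus"] == "none").all():
        raise ValueError("controls must have focus=none")
    if (t.loc[~hc, "focus"] == "none").any():
        raise ValueError("patients must have focus in {left, right}")
    if (t["age"] <= 0).any():
        raise ValueError("ages must be positive")
    if "duration" in t.columns:
        d = t["duration"].to_numpy(float)
        ok = np.isnan(d) | (d <= t["age"].to_numpy(float))
        if not ok.all():
            raise ValueError("disease duration cannot exceed age")
    return t


def read_subjects(path) -> pd.DataFrame:
    return validate_subjects(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Lateralization and lobe aggregation
# ---------------------------------------------------------------------------

def lateralize_to_focus(values: np.ndarray, subjects: pd.DataFrame, atlas: Atlas) -> np.ndarray:
    """Re-order region columns so homologue pairs read (ipsilateral, contralateral).

    For right-focus subjects the values of each left/right homologue pair are
    swapped; left-focus rows and midline columns are untouched.  After the
    swap, a column that was "left hemisphere" holds the ipsilateral member of
    its pair for every subject.

    Parameters
    ----------
    values : (n_subjects, n_regions) array in canonical atlas order.
    subjects : subject table aligned with the rows of ``values``.
    atlas : the parcellation.
    """
    values = np.asarray(values)
    if values.shape[0] != len(subjects):
        raise ValueError("subject table does not match value rows")
    focus = subjects["focus"].to_numpy()
    if (focus == "none").any():
        raise ValueError("cannot lateralize subjects with focus=none (controls)")
    perm = atlas.swap_permutation()
    out = values.copy()
    right = focus == "right"
    out[np.ix_(right, np.arange(values.shape[1]))] = values[right][:, perm]
    return out


def lobe_aggregate(region_values: np.ndarray, atlas: Atlas, stat: str = "mean") -> pd.DataFrame:
    """Aggregate a region-indexed map into a lobe x hemisphere table.

    ``stat`` is ``mean``, ``count`` (sum of truthy entries) or ``proportion``
    (count divided by the number of regions in that lobe/hemisphere cell).
    """
    if stat not in ("mean", "count", "proportion"):
        raise ValueError(f"unknown stat {stat!r}")
    region_values = np.asarray(region_values, float)
    if region_values.shape[-1] != atlas.n_regions:
        raise ValueError("map does not cover all atlas regions")
    t = atlas.table
    rows = []
    for lobe in LOBES:
        for hemi in ("left", "right"):
            sel = ((t["lobe"] == lobe) & (t["hemisphere"] == hemi)).to_numpy()
            if not sel.any():
                continue
            vals = region_values[..., sel]
            if stat == "mean":
                agg = vals.mean(axis=-1)
            elif stat == "count":
                agg = (vals != 0).sum(axis=-1)
            else:
                agg = (vals != 0).sum(axis=-1) / sel.sum()
            rows.append({"lobe": lobe, "hemisphere": hemi,
                         "n_regions": int(sel.sum()), "value": agg})
    return pd.DataFrame(rows)
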