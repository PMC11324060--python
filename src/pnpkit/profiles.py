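"""Morphological (cell-painting) profile triage.

Profiles are vectors of 579 image features per compound/concentration,
modified-Z-scored against solvent (DMSO) controls. Induction — the percent of
features significantly changed — measures overall bioactivity; active
profiles (induction >= 5%) are assigned to reference bioactivity clusters by
Pearson correlation on cluster-specific feature subsets ("subprofiles"), with
an 80% similarity threshold. Actives matching no cluster are candidates for
novel bioactivity and can be embedded in 2-D together with cluster marker
compounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_FEATURES = 579
DEFAULT_SIGNIFICANCE = 3.0  # |modified Z| at which a feature counts as changed
DEFAULT_MIN_INDUCTION = 5.0  # percent
DEFAULT_MIN_SIMILARITY = 80.0  # percent


@dataclass
class MorphProfile:
    compound_id: str
    concentration: float
    features: np.ndarray  # shape (N_FEATURES,)
    induction: float | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)


@dataclass
class ClusterSubprofile:
    cluster_name: str
    feature_subset: np.ndarray  # sorted unique indices into the full profile
    values: np.ndarray  # median reference vector on the subset

    def __post_init__(self) -> None:
        self.feature_subset = np.asarray(self.feature_subset, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_subset.size == 0:
            raise ValueError(f"cluster {self.cluster_name}: empty feature subset")
        if len(np.unique(self.feature_subset)) != len(self.feature_subset):
            raise ValueError(f"cluster {self.cluster_name}: duplicate feature indices")
        if self.feature_subset.shape != self.values.shape:
            raise ValueError(f"cluster {self.cluster_name}: subset/values length mismatch")


def compute_induction(
    features: np.ndarray,
    significance_threshold: float = DEFAULT_SIGNIFICANCE,
    n_features: int = N_FEATURES,
) -> float:
    """Percent of features with |value| >= threshold, relative to the full
    profile length."""
    features = np.asarray(features, dtype=float)
    if features.shape != (n_features,):
        raise ValueError(f"expected {n_features} features, got {features.shape}")
    return 100.0 * float(np.sum(np.abs(features) >= significance_threshold)) / n_features


def flag_active(profile: MorphProfile, min_induction: float = DEFAULT_MIN_INDUCTION) -> bool:
    """True iff the profile's induction is at or above the activity cutoff."""
    if profile.induction is None:
        raise ValueError("induction not computed")
    return profile.induction >= min_induction


def subprofile_similarity(features: np.ndarray, subprofile: ClusterSubprofile) -> float:
    """100 x Pearson correlation between the profile restricted to the
    cluster's feature subset and the cluster's reference values.

    A constant restricted vector has undefined correlation and is treated as
    -100 (always below any sensible threshold)."""
    restricted = np.asarray(features, dtype=float)[subprofile.feature_subset]
    if np.std(restricted) == 0 or np.std(subprofile.values) == 0:
        logger.info("constant subprofile vector for %s", subprofile.cluster_name)
        return -100.0
    return 100.0 * float(np.corrcoef(restricted, subprofile.values)[0, 1])


def assign_cluster(
    profile: MorphProfile,
    subprofiles: Sequence[ClusterSubprofile],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> tuple[str | None, float]:
    """Best cluster by subprofile similarity, or unassigned (None).

    Ties on similarity resolve to the lexicographically smaller cluster name.
    Returns (cluster_name or None, best similarity).
    """
    best_name: str | None = None
    best_sim = -np.inf
    for sp in sorted(subprofiles, key=lambda s: s.cluster_name):
        sim = subprofile_similarity(profile.features, sp)
        if sim > best_sim:
            best_name, best_sim = sp.cluster_name, sim
    if best_name is None or best_sim < min_similarity:
        return None, float(best_sim)
    return best_name, float(best_sim)


def embed_profiles(
    profiles: Sequence[MorphProfile],
    markers: Sequence[MorphProfile] = (),
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """Joint 2-D UMAP embedding of profiles and cluster-marker profiles.

    Deterministic for a fixed seed. Returns a frame with columns
    ``id``, ``kind`` (profile/marker), ``x``, ``y``.
    """
    import umap  # deferred: heavy import

    everything = list(profiles) + list(markers)
    if len(everything) < 2:
        raise ValueError("embedding requires at least 2 profiles")
    X = np.vstack([p.features for p in everything])
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(everything) - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(X)
    return pd.DataFrame(
        {
            "id": [p.compound_id for p in everything],
            "kind": ["profile"] * len(profiles) + ["marker"] * len(markers),
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# I/O


def read_profiles(
    path: str | Path, significance_threshold: float = DEFAULT_SIGNIFICANCE
) -> list[MorphProfile]:
    """Read a profile TSV (columns: id, concentration, then feature columns)
    and compute induction for every row."""
    df = pd.read_csv(path, sep="\t")
    feature_cols = [c for c in df.columns if c not in ("id", "concentration")]
    profiles = []
    for _, row in df.iterrows():
        features = row[feature_cols].to_numpy(dtype=float)
        p = MorphProfile(
            compound_id=str(row["id"]),
            concentration=float(row["concentration"]),
            features=features,
        )
        p.induction = compute_induction(
            features, significance_threshold, n_features=len(feature_cols)
        )
        profiles.append(p)
    return profiles


def write_profiles(profiles: Sequence[MorphProfile], path: str | Path) -> None:
    n = len(profiles[0].features)
    cols = [f"f{i:03d}" for i in range(n)]
    df = pd.DataFrame([p.features for p in profiles], columns=cols)
    df.insert(0, "concentration", [p.concentration for p in profiles])
    df.insert(0, "id", [p.compound_id for p in profiles])
    df.to_csv(path, sep="\t", index=False)


def read_subprofiles(path: str | Path) -> list[ClusterSubprofile]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        ClusterSubprofile(
            cluster_name=entry["cluster_name"],
            feature_subset=np.asarray(entry["feature_subset"], dtype=int),
            values=np.asarray(entry["values"], dtype=float),
        )
        for entry in data
    ]


def write_subprofiles(subprofiles: Sequence[ClusterSubprofile], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "cluster_name": sp.cluster_name,
                    "feature_subset": [int(i) for i in sp.feature_subset],
                    "values": [float(v) for v in sp.values],
                }
                for sp in subprofiles
            ],
            fh,
        )
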