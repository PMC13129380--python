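"""Core data types for cell-feature bags and cohorts.

A slide is represented as a *bag* of instances, one instance per detected
cell: a feature vector ``x_i`` of cohort-wide dimension ``M``, a patch
quality score ``s_i`` in [0, 1], and an optional cell-level class label.
A *cohort* is a collection of bags sharing ``M`` and the number of bag
classes ``C``.

Storage is a plain-text directory container:

``instances.csv``
    columns ``bag_id, patch_id, cell_label, quality, f_0 .. f_{M-1}``;
    rows of one bag are contiguous and their order is preserved.
``bags.csv``
    columns ``bag_id, label`` (one row per bag, including empty bags).
``meta.yaml``
    keys ``C``, ``M``, ``split_tag``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

NORMAL = "normal"
ABNORMAL = "abnormal"
UNKNOWN = "unknown"
CELL_LABELS = (NORMAL, ABNORMAL, UNKNOWN)

INSTANCE_FILE = "instances.csv"
BAG_FILE = "bags.csv"
META_FILE = "meta.yaml"


class CohortValidationError(ValueError):
    """An invariant of the bag/cohort container is violated."""


@dataclass
class Instance:
    """One detected cell: feature vector, patch quality score, optional label."""

    feature: np.ndarray
    quality: float
    cell_label: str = UNKNOWN
    patch_id: str = ""

    def __post_init__(self) -> None:
        self.feature = np.asarray(self.feature, dtype=float)


@dataclass
class Bag:
    """One slide: an ordered set of instances and a bag-level class label.

    Features are stored as a dense ``(K, M)`` array; ``K`` may be 0 (a slide
    emptied by quality screening is representable).
    """

    bag_id: str
    features: np.ndarray          # (K, M)
    qualities: np.ndarray         # (K,)
    cell_labels: list[str]
    patch_ids: list[str]
    label: int

    @property
    def K(self) -> int:
        return self.features.shape[0]

    @property
    def M(self) -> int:
        return self.features.shape[1]

    @property
    def instances(self) -> list[Instance]:
        return [
            Instance(self.features[i], float(self.qualities[i]),
                     self.cell_labels[i], self.patch_ids[i])
            for i in range(self.K)
        ]

    @classmethod
    def from_instances(cls, bag_id: str, instances: list[Instance], label: int,
                       M: int | None = None) -> "Bag":
        if instances:
            M = instances[0].feature.shape[0] if M is None else M
            feats = np.stack([inst.feature for inst in instances])
        else:
            if M is None:
                raise CohortValidationError(
                    f"bag {bag_id!r}: feature dimension M required for an empty bag")
            feats = np.empty((0, M))
        return cls(
            bag_id=bag_id,
            features=feats,
            qualities=np.array([inst.quality for inst in instances], dtype=float),
            cell_labels=[inst.cell_label for inst in instances],
            patch_ids=[inst.patch_id for inst in instances],
            label=int(label),
        )

    def validate(self, M: int, C: int) -> None:
        if self.features.ndim != 2 or self.features.shape[1] != M:
            raise CohortValidationError(
                f"bag {self.bag_id!r}: feature dimension "
                f"{self.features.shape} inconsistent with cohort M={M}")
        if not np.all(np.isfinite(self.features)):
            raise CohortValidationError(
                f"bag {self.bag_id!r}: non-finite feature entries")
        if self.qualities.shape != (self.K,):
            raise CohortValidationError(
                f"bag {self.bag_id!r}: quality vector shape mismatch")
        if self.K and (np.min(self.qualities) < 0 or np.max(self.qualities) > 1):
            raise CohortValidationError(
                f"bag {self.bag_id!r}: quality score outside [0, 1]")
        if len(self.cell_labels) != self.K or len(self.patch_ids) != self.K:
            raise CohortValidationError(
                f"bag {self.bag_id!r}: per-instance metadata length mismatch")
        for lab in self.cell_labels:
            if lab not in CELL_LABELS:
                raise CohortValidationError(
                    f"bag {self.bag_id!r}: unknown cell_label {lab!r}")
        if not (0 <= self.label < C):
            raise CohortValidationError(
                f"bag {self.bag_id!r}: bag label {self.label} outside 0..{C - 1}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bag):
            return NotImplemented
        return (self.bag_id == other.bag_id
                and self.label == other.label
                and self.features.shape == other.features.shape
                and np.array_equal(self.features, other.features)
                and np.array_equal(self.qualities, other.qualities)
                and self.cell_labels == other.cell_labels
                and self.patch_ids == other.patch_ids)


@dataclass
class Cohort:
    """A collection of bags sharing feature dimension M and class count C."""

    bags: list[Bag] = field(default_factory=list)
    C: int = 2
    M: int = 0
    split_tag: str = "train"

    def validate(self) -> None:
        if self.split_tag not in ("train", "validation", "test"):
            raise CohortValidationError(f"invalid split_tag {self.split_tag!r}")
        if self.C < 1:
            raise CohortValidationError("C must be >= 1")
        seen: set[str] = set()
        for bag in self.bags:
            if bag.bag_id in seen:
                raise CohortValidationError(f"duplicate bag_id {bag.bag_id!r}")
            seen.add(bag.bag_id)
            bag.validate(self.M, self.C)

    @property
    def n_bags(self) -> int:
        return len(self.bags)

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags], dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (self.C == other.C and self.M == other.M
                and self.split_tag == other.split_tag
                and self.bags == other.bags)


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write a validated cohort to the directory container at ``path``."""
    cohort.validate()
    os.makedirs(path, exist_ok=True)

    feat_cols = [f"f_{j}" for j in range(cohort.M)]
    rows = []
    for bag in cohort.bags:
        for i in range(bag.K):
            rows.append((bag.bag_id, bag.patch_ids[i], bag.cell_labels[i],
                         bag.qualities[i], *bag.features[i]))
    inst = pd.DataFrame(rows, columns=["bag_id", "patch_id", "cell_label",
                                       "quality", *feat_cols])
    # repr-precision floats so that read_cohort inverts to full stored precision
    inst.to_csv(os.path.join(path, INSTANCE_FILE), index=False,
                float_format="%.17g")

    bags = pd.DataFrame({"bag_id": [b.bag_id for b in cohort.bags],
                         "label": [b.label for b in cohort.bags]})
    bags.to_csv(os.path.join(path, BAG_FILE), index=False)

    with open(os.path.join(path, META_FILE), "w", encoding="utf-8") as fh:
        yaml.safe_dump({"C": cohort.C, "M": cohort.M,
                        "split_tag": cohort.split_tag}, fh)


def read_cohort(path: str) -> Cohort:
    """Read and validate a cohort from the directory container at ``path``.

    Instance order within each bag is preserved exactly as stored.
    """
    for fname in (INSTANCE_FILE, BAG_FILE, META_FILE):
        if not os.path.exists(os.path.join(path, fname)):
            raise FileNotFoundError(f"missing cohort file {fname} under {path}")

    with open(os.path.join(path, META_FILE), encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    for key in ("C", "M", "split_tag"):
        if key not in meta:
            raise CohortValidationError(f"metadata missing key {key!r}")
    C, M, split_tag = int(meta["C"]), int(meta["M"]), str(meta["split_tag"])

    bag_df = pd.read_csv(os.path.join(path, BAG_FILE),
                         dtype={"bag_id": str, "label": int})
    if list(bag_df.columns) != ["bag_id", "label"]:
        raise CohortValidationError(f"bag table columns {list(bag_df.columns)} "
                                    "!= ['bag_id', 'label']")

    feat_cols = [f"f_{j}" for j in range(M)]
    expected = ["bag_id", "patch_id", "cell_label", "quality", *feat_cols]
    inst_df = pd.read_csv(os.path.join(path, INSTANCE_FILE),
                          float_precision="round_trip",
                          dtype={"bag_id": str, "patch_id": str,
                                 "cell_label": str})
    if list(inst_df.columns) != expected:
        missing = set(expected) - set(inst_df.columns)
        raise CohortValidationError(
            f"instance table columns mismatch (missing or extra: "
            f"{sorted(missing) or list(inst_df.columns)})")

    known_bags = set(bag_df["bag_id"])
    groups = ({} if inst_df.empty else
              {str(k): g for k, g in inst_df.groupby("bag_id", sort=False)})
    for bid in groups:
        if bid not in known_bags:
            raise CohortValidationError(
                f"bag {bid!r}: instances present but bag not in bag table")

    bags = []
    for bid, label in zip(bag_df["bag_id"], bag_df["label"]):
        g = groups.get(bid)
        if g is None:
            bags.append(Bag(bid, np.empty((0, M)), np.empty(0), [], [],
                            int(label)))
            continue
        feats = g[feat_cols].to_numpy(dtype=float)
        bags.append(Bag(
            bag_id=bid,
            features=feats,
            qualities=g["quality"].to_numpy(dtype=float),
            cell_labels=[str(x) for x in g["cell_label"]],
            patch_ids=[str(x) for x in g["patch_id"]],
            label=int(label),
        ))

    cohort = Cohort(bags=bags, C=C, M=M, split_tag=split_tag)
    cohort.validate()
    return cohort
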