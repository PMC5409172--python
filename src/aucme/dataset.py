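"""Long-format container for replicate biomarker measurements.

One row per measurement: subject identifier, group label (``case`` or
``control``), replicate index (1-based), and the marker value.  Replicates
must be distinguishable — the replicate index identifies which collection a
value came from — because the probit-scale ICC transforms each replicate
column on its own scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .icc_estimation import ReplicateTable

__all__ = ["BiomarkerDataset", "GROUPS"]

GROUPS = ("case", "control")


@dataclass(frozen=True)
class BiomarkerDataset:
    """Validated long-format biomarker data.

    ``frame`` has columns ``subject_id``, ``group``, ``replicate``,
    ``value``; ``(subject_id, replicate)`` pairs are unique and every
    subject belongs to exactly one group.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = ["subject_id", "group", "replicate", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        dup = df.duplicated(subset=["subject_id", "replicate"])
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "replicate"]].values.tolist()
            raise ValueError(f"duplicate (subject, replicate) pairs: {pairs[:10]}")
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group labels: {bad}; expected {GROUPS}")
        ngroups = df.groupby("subject_id")["group"].nunique()
        if (ngroups > 1).any():
            offenders = ngroups[ngroups > 1].index.tolist()
            raise ValueError(f"subjects in more than one group: {offenders[:10]}")
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise ValueError("marker values must be finite")

    @classmethod
    def from_arrays(cls, cases: np.ndarray, controls: np.ndarray) -> "BiomarkerDataset":
        """Build from balanced subjects x replicates matrices per group."""
        cases = np.atleast_2d(np.asarray(cases, dtype=float))
        controls = np.atleast_2d(np.asarray(controls, dtype=float))
        rows = []
        for mat, group, tag in ((cases, "case", "x"), (controls, "control", "y")):
            s, k = mat.shape
            for i in range(s):
                for r in range(k):
                    rows.append((f"{tag}{i + 1:04d}", group, r + 1, mat[i, r]))
        frame = pd.DataFrame(
            rows, columns=["subject_id", "group", "replicate", "value"]
        )
        return cls(frame)

    @property
    def n_subjects(self) -> int:
        return int(self.frame["subject_id"].nunique())

    def n_in_group(self, group: str) -> int:
        sub = self.frame[self.frame["group"] == group]
        return int(sub["subject_id"].nunique())

    def primary_values(self, group: str, primary_replicate: int = 1) -> np.ndarray:
        """The designated primary measurement per subject for one group.

        Raises if any subject of the group lacks the primary replicate;
        replicates beyond the primary feed only the ICC machinery.
        """
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise ValueError(f"no measurements for group {group!r}")
        primary = sub[sub["replicate"] == primary_replicate]
        missing = set(sub["subject_id"]) - set(primary["subject_id"])
        if missing:
            raise ValueError(
                f"subjects missing primary replicate {primary_replicate}: "
                f"{sorted(missing)[:10]}"
            )
        return primary.sort_values("subject_id")["value"].to_numpy(dtype=float)

    def replicate_table(self, group: str) -> ReplicateTable:
        """Raw-scale per-subject replicate table for one group."""
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise ValueError(f"no measurements for group {group!r}")
        return ReplicateTable.from_flat(
            sub["subject_id"].to_numpy(), sub["value"].to_numpy(dtype=float)
        )

    def replicate_matrix(self, group: str) -> np.ndarray:
        """Balanced subjects x replicates matrix; raises if unbalanced."""
        sub = self.frame[self.frame["group"] == group]
        wide = sub.pivot(index="subject_id", columns="replicate", values="value")
        if wide.isna().any().any():
            raise ValueError(f"group {group!r} replicates are unbalanced")
        return wide.to_numpy(dtype=float)

    def has_replicates(self, group: str) -> bool:
        sub = self.frame[self.frame["group"] == group]
        counts = sub.groupby("subject_id").size()
        return int((counts >= 2).sum()) >= 2
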