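"""Expression-matrix container (features x observations) used across the package.

The container is deliberately thin: a dense float array plus identifier
lists and optional per-observation group labels.  Algorithms index into
``values`` directly; I/O converts to and from pandas / MatrixMarket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


def _check_unique(ids: list[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """A features x observations numeric matrix.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_observations)
        Log-scale expression or normalized counts; must be finite.
    feature_ids, observation_ids : lists of unique identifiers.
    group_labels : optional dict observation_id -> group name.  When present
        every observation must be labeled; used for group-level analysis.
    """

    values: np.ndarray
    feature_ids: list[str]
    observation_ids: list[str]
    group_labels: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x observations)")
        f, n = self.values.shape
        if f == 0:
            raise ValueError("no features")
        if n == 0:
            raise ValueError("no observations")
        self.feature_ids = [str(x) for x in self.feature_ids]
        self.observation_ids = [str(x) for x in self.observation_ids]
        if len(self.feature_ids) != f:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {f} rows")
        if len(self.observation_ids) != n:
            raise ValueError(f"{len(self.observation_ids)} observation ids for {n} columns")
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.observation_ids, "observation_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.group_labels is not None:
            missing = [o for o in self.observation_ids if o not in self.group_labels]
            if missing:
                raise ValueError(f"observations without a group label: {missing[:10]}")
            self.group_labels = {o: str(self.group_labels[o]) for o in self.observation_ids}

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_observations(self) -> int:
        return self.values.shape[1]

    def groups(self) -> dict[str, list[str]]:
        """Map group name -> member observation ids (insertion order of observations)."""
        if self.group_labels is None:
            raise ValueError("matrix has no group labels")
        out: dict[str, list[str]] = {}
        for o in self.observation_ids:
            out.setdefault(self.group_labels[o], []).append(o)
        return out

    def subset_observations(self, keep: list[str]) -> "ExpressionMatrix":
        idx = {o: i for i, o in enumerate(self.observation_ids)}
        cols = [idx[o] for o in keep]
        gl = None
        if self.group_labels is not None:
            gl = {o: self.group_labels[o] for o in keep}
        return ExpressionMatrix(self.values[:, cols], list(self.feature_ids), list(keep), gl)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.observation_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   group_labels: dict[str, str] | None = None) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index],
                   [str(c) for c in df.columns], group_labels)
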