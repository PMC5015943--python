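"""Genome map and founder-dosage containers.

A :class:`GenomeMap` holds marker positions (Mb) per chromosome. A
:class:`FounderDosageMap` holds, for every marker, an ``n_mice x 8``
matrix of expected founder-allele counts (rows sum to 2), the input of
the additive haplotype-regression genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import FOUNDER_COLUMNS, N_FOUNDERS

ROW_SUM_TOL = 1e-6


@dataclass
class GenomeMap:
    """Ordered chromosomes with marker positions in Mb.

    Parameters
    ----------
    chromosomes : list of (name, length_mb)
        Chromosome names and physical lengths in megabases.
    markers : dict mapping chromosome name -> array of positions (Mb)
        Positions must be strictly increasing and lie in [0, length].
    """

    chromosomes: list[tuple[str, float]]
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("GenomeMap requires a non-empty chromosome list")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            pos = np.asarray(self.markers.get(name, []), dtype=float)
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker positions on chromosome {name!r} must be strictly increasing"
                )
            self.markers[name] = pos

    @classmethod
    def uniform(
        cls,
        chromosomes: list[tuple[str, float]],
        n_markers_per_chrom: int,
    ) -> "GenomeMap":
        """Evenly spaced markers along each chromosome."""
        markers = {
            name: np.linspace(0.0, length, n_markers_per_chrom + 2)[1:-1]
            for name, length in chromosomes
        }
        return cls(chromosomes=chromosomes, markers=markers)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.markers.values())

    def marker_table(self) -> pd.DataFrame:
        """All markers as a DataFrame (marker_id, chrom, pos_mb)."""
        rows = []
        for name, _ in self.chromosomes:
            for i, p in enumerate(self.markers[name]):
                rows.append((f"{name}_{i:05d}", name, float(p)))
        return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_mb"])


@dataclass
class FounderDosageMap:
    """Per-marker expected founder-allele dosages for a population.

    Attributes
    ----------
    markers : DataFrame with columns marker_id, chrom, pos_mb
        Ordered marker list; positions increase within each chromosome.
    dosages : ndarray of shape (n_markers, n_mice, 8)
        Expected count of each founder allele in each mouse's diplotype;
        every row sums to 2.
    mouse_ids : list of str
    """

    markers: pd.DataFrame
    dosages: np.ndarray
    mouse_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 3 or self.dosages.shape[2] != N_FOUNDERS:
            raise ValueError("dosages must have shape (n_markers, n_mice, 8)")
        if len(self.markers) != self.dosages.shape[0]:
            raise ValueError("marker table and dosage array disagree on marker count")
        if len(self.mouse_ids) != self.dosages.shape[1]:
            raise ValueError("mouse_ids and dosage array disagree on mouse count")

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_mice(self) -> int:
        return self.dosages.shape[1]

    def validate(self, tol: float = ROW_SUM_TOL) -> None:
        """Check dosage conservation (rows sum to 2) and position order."""
        sums = self.dosages.sum(axis=2)
        if not np.allclose(sums, 2.0, atol=tol):
            bad = np.argwhere(np.abs(sums - 2.0) > tol)[0]
            raise ValueError(
                f"dosage row does not sum to 2 at marker {bad[0]}, mouse {bad[1]}"
            )
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos_mb"].to_numpy()) < 0):
                raise ValueError(f"marker positions decrease on chromosome {chrom}")

    def subset_mice(self, keep: np.ndarray) -> "FounderDosageMap":
        """Restrict to a boolean/index subset of mice."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            ids = [m for m, k in zip(self.mouse_ids, keep) if k]
        else:
            ids = [self.mouse_ids[i] for i in keep]
        return FounderDosageMap(
            markers=self.markers.reset_index(drop=True),
            dosages=self.dosages[:, keep, :],
            mouse_ids=ids,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per mouse x marker with 8 dosage columns."""
        m, n, _ = self.dosages.shape
        rec = self.markers.loc[self.markers.index.repeat(n)].reset_index(drop=True)
        rec.insert(0, "mouse_id", np.tile(self.mouse_ids, m))
        flat = self.dosages.reshape(m * n, N_FOUNDERS)
        for j, col in enumerate(FOUNDER_COLUMNS):
            rec[col] = flat[:, j]
        return rec[["mouse_id", "chrom", "pos_mb", "marker_id", *FOUNDER_COLUMNS]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FounderDosageMap":
        mouse_ids = list(pd.unique(df["mouse_id"]))
        marker_ids = list(pd.unique(df["marker_id"]))
        n, m = len(mouse_ids), len(marker_ids)
        if len(df) != n * m:
            raise ValueError("dosage table is not a complete mouse x marker grid")
        df = df.copy()
        df["_mi"] = df["marker_id"].map({k: i for i, k in enumerate(marker_ids)})
        df["_ni"] = df["mouse_id"].map({k: i for i, k in enumerate(mouse_ids)})
        df = df.sort_values(["_mi", "_ni"])
        dosages = df[list(FOUNDER_COLUMNS)].to_numpy(float).reshape(m, n, N_FOUNDERS)
        markers = (
            df.drop_duplicates("marker_id")[["marker_id", "chrom", "pos_mb"]]
            .astype({"chrom": str})
            .reset_index(drop=True)
        )
        return cls(markers=markers, dosages=dosages, mouse_ids=mouse_ids)

    @classmethod
    def from_csv(cls, path) -> "FounderDosageMap":
        return cls.from_frame(pd.read_csv(path, dtype={"chrom": str}))
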