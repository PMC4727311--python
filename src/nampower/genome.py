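"""Genetic map: marker coordinates shared by every simulation stage.

Positions are carried both physically (bp) and genetically (cM).  When only
physical positions are known, genetic positions are obtained by the linear
conversion used for *Brassica napus*, 0.674 Mb per cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Physical-to-genetic conversion rate for the B. napus genome, in bp per cM.
BP_PER_CM = 674_000.0


def bp_to_cm(pos_bp):
    """Convert physical position(s) in bp to genetic position(s) in cM.

    Linear conversion at 0.674 Mb/cM.  Accepts scalars or arrays; positions
    must be non-negative.
    """
    pos = np.asarray(pos_bp, dtype=float)
    if np.any(pos < 0):
        raise ValueError("physical positions must be >= 0")
    out = pos / BP_PER_CM
    return float(out) if np.isscalar(pos_bp) else out


@dataclass
class GeneticMap:
    """Marker map sorted by (chromosome, cM position).

    Parameters
    ----------
    table:
        DataFrame with columns ``marker_id``, ``chromosome``, ``pos_bp``,
        ``pos_cm``.  If ``pos_cm`` is absent it is derived from ``pos_bp``
        at 0.674 Mb/cM.  Rows are sorted on construction; an unsorted input
        is accepted and normalised.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = {"marker_id", "chromosome", "pos_bp"}
        missing = required - set(df.columns)
        if missing and "pos_cm" not in df.columns:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if "pos_bp" not in df.columns:
            df["pos_bp"] = np.round(df["pos_cm"].to_numpy(float) * BP_PER_CM).astype(np.int64)
        if "pos_cm" not in df.columns:
            df["pos_cm"] = bp_to_cm(df["pos_bp"].to_numpy())
        if (df["pos_bp"].to_numpy() < 0).any():
            raise ValueError("physical positions must be >= 0")
        df["chromosome"] = df["chromosome"].astype(str)
        df = df.sort_values(["chromosome", "pos_cm"], kind="stable").reset_index(drop=True)
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup!r}")
        self.table = df

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosome(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def pos_cm(self) -> np.ndarray:
        return self.table["pos_cm"].to_numpy(float)

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (map is sorted)."""
        out: dict[str, slice] = {}
        chroms = self.chromosome
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def subset(self, idx) -> "GeneticMap":
        return GeneticMap(self.table.iloc[np.asarray(idx)].reset_index(drop=True))

    @classmethod
    def uniform(
        cls,
        chrom_lengths_cm: dict[str, float],
        n_markers: int,
    ) -> "GeneticMap":
        """Evenly spaced markers, per-chromosome counts proportional to length.

        Largest-remainder apportionment guarantees the counts sum exactly to
        ``n_markers``.
        """
        counts = apportion_markers(chrom_lengths_cm, n_markers)
        rows = []
        for chrom, length in chrom_lengths_cm.items():
            k = counts[chrom]
            if k == 0:
                continue
            # even spacing: midpoints of k equal bins over [0, length]
            pos_cm = (np.arange(k) + 0.5) * (length / k)
            for j, p in enumerate(pos_cm):
                rows.append((f"{chrom}_m{j + 1}", chrom, int(round(p * BP_PER_CM)), p))
        return cls(pd.DataFrame(rows, columns=["marker_id", "chromosome", "pos_bp", "pos_cm"]))


def apportion_markers(chrom_lengths_cm: dict[str, float], n_total: int) -> dict[str, int]:
    """Split ``n_total`` markers across chromosomes proportionally to length.

    Largest-remainder rounding, so the result sums exactly to ``n_total``.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    lengths = np.array(list(chrom_lengths_cm.values()), float)
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    quota = n_total * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    short = n_total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return dict(zip(chrom_lengths_cm.keys(), base.tolist()))
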