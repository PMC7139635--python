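"""Genotype matrices, recombination fractions and Kosambi genetic maps.

Markers are realized at window midpoints; marker order is fixed to
physical order (maps are anchored to the reference assembly, no de-novo
grouping or ordering). Adjacent-interval recombination fractions are the
proportion of lines whose genotypes differ between two neighbouring
markers. For DH populations each line is a single meiotic gamete and the
observed fraction estimates the single-meiosis r directly; for selfed
RILs the observed fraction R is inflated by the extra meioses and is
corrected back with the Haldane–Waddington selfing result
``r = R / (2 - 2R)`` before applying the Kosambi map function

    cM = 25 * ln((1 + 2r) / (1 - 2r)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome, WindowGrid
from .schemes import Population

__all__ = [
    "GenotypeMatrix",
    "LinkageMap",
    "genotype_matrix",
    "adjacent_recfrac",
    "kosambi",
    "ril_correction",
    "build_linkage_map",
    "map_correlation",
]

_R_CLIP = 0.4999  # Kosambi diverges at r = 0.5


@dataclass(frozen=True)
class GenotypeMatrix:
    """Lines x markers founder codes with a physical marker table.

    ``markers`` has columns chrom, pos (bp, window midpoints, strictly
    increasing within chromosome); ``codes`` is an (n_lines, n_markers)
    integer array of founder labels.
    """

    markers: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        if self.codes.shape[1] != len(self.markers):
            raise ValueError("codes width does not match marker table")

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def to_frame(self, biallelic_letters: bool = True) -> pd.DataFrame:
        cols = [f"{c}_{int(p)}" for c, p in
                zip(self.markers["chrom"], self.markers["pos"])]
        values = self.codes
        if biallelic_letters and values.max(initial=0) <= 1:
            values = np.array(["A", "B"])[values]
        df = pd.DataFrame(values, columns=cols)
        df.insert(0, "line", [f"L{i + 1}" for i in range(self.n_lines)])
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def genotype_matrix(pop: Population, grid: WindowGrid) -> GenotypeMatrix:
    """Score every line's consensus mosaic at each window midpoint."""
    marker_rows = []
    for chrom in pop.genome.ids:
        mids = grid.midpoints(chrom)
        marker_rows.append(pd.DataFrame({"chrom": chrom, "pos": mids}))
    markers = pd.concat(marker_rows, ignore_index=True)

    mosaics = pop.mosaics()
    codes = np.empty((len(pop), len(markers)), dtype=np.int64)
    col = 0
    for chrom in pop.genome.ids:
        mids = grid.midpoints(chrom)
        for i, mosaic in enumerate(mosaics):
            codes[i, col:col + len(mids)] = mosaic.founders_at(chrom, mids)
        col += len(mids)
    return GenotypeMatrix(markers, codes)


def read_genotype_csv(path) -> GenotypeMatrix:
    """Read a genotype CSV written by :meth:`GenotypeMatrix.to_csv`."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"genotype CSV {path} has no marker columns")
    chroms, poss = [], []
    for name in df.columns[1:]:
        try:
            chrom, pos = name.rsplit("_", 1)
            poss.append(float(pos))
        except ValueError:
            raise ValueError(f"malformed marker column name {name!r}") from None
        chroms.append(chrom)
    values = df.iloc[:, 1:].to_numpy()
    if values.dtype.kind in "OU":
        letters = np.unique(values)
        lut = {v: i for i, v in enumerate(letters)}
        values = np.vectorize(lut.__getitem__)(values)
    markers = pd.DataFrame({"chrom": chroms, "pos": poss})
    return GenotypeMatrix(markers, values.astype(np.int64))


def adjacent_recfrac(matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Recombination fraction per adjacent-marker interval, per chromosome.

    r = proportion of lines whose founder codes differ between the two
    markers of the interval.
    """
    out = {}
    for chrom in matrix.chroms:
        sl = matrix.chrom_slice(chrom)
        sub = matrix.codes[:, sl]
        if sub.shape[1] < 2:
            raise ValueError(f"chromosome {chrom!r} has fewer than 2 markers")
        out[chrom] = np.mean(sub[:, 1:] != sub[:, :-1], axis=0)
    return out


def kosambi(r) -> np.ndarray | float:
    """Kosambi map function: cM = 25 * ln((1 + 2r) / (1 - 2r)).

    Values outside [0, 0.4999] are clipped with a warning.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > _R_CLIP):
        warnings.warn(
            f"recombination fraction(s) outside [0, {_R_CLIP}] clipped "
            "before Kosambi transform",
            stacklevel=2,
        )
        r_arr = np.clip(r_arr, 0.0, _R_CLIP)
    cm = 25.0 * np.log((1.0 + 2.0 * r_arr) / (1.0 - 2.0 * r_arr))
    return float(cm) if np.isscalar(r) or np.ndim(r) == 0 else cm


def ril_correction(R) -> np.ndarray | float:
    """Invert the selfing-RIL relation R = 2r / (1 + 2r): r = R / (2 - 2R)."""
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr >= 0.5):
        warnings.warn("observed RIL fraction(s) >= 0.5 clipped before correction",
                      stacklevel=2)
        R_arr = np.clip(R_arr, 0.0, 0.5 - 1e-9)
    r = R_arr / (2.0 - 2.0 * R_arr)
    return float(r) if np.isscalar(R) or np.ndim(R) == 0 else r


@dataclass(frozen=True)
class LinkageMap:
    """Cumulative Kosambi positions at physically ordered markers.

    ``table`` columns: chrom, pos (bp), cm (cumulative within
    chromosome, non-decreasing).
    """

    table: pd.DataFrame
    pop_type: str

    @property
    def total_length_cm(self) -> float:
        return float(self.table.groupby("chrom", sort=False)["cm"].max().sum())

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["pos"] = out["pos"].astype(np.int64)
        out["cm"] = out["cm"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", header=["chrom", "position_bp",
                                           "cumulative_cM"], index=False)


def build_linkage_map(matrix: GenotypeMatrix, pop_type: str = "DH") -> LinkageMap:
    """Kosambi map from adjacent-marker fractions, physical order fixed.

    pop_type "DH": observed fractions are single-meiosis r. pop_type
    "RIL": observed fractions are corrected with r = R / (2 - 2R) first.
    """
    pop_type = pop_type.upper()
    if pop_type not in {"DH", "RIL"}:
        raise ValueError(f"unknown population type {pop_type!r}")
    fracs = adjacent_recfrac(matrix)
    pieces = []
    for chrom in matrix.chroms:
        r = fracs[chrom]
        if pop_type == "RIL":
            r = ril_correction(r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            interval_cm = kosambi(np.asarray(r))
        cm = np.concatenate([[0.0], np.cumsum(interval_cm)])
        sl = matrix.chrom_slice(chrom)
        pieces.append(pd.DataFrame({
            "chrom": chrom,
            "pos": matrix.markers["pos"].to_numpy()[sl],
            "cm": cm,
        }))
    return LinkageMap(pd.concat(pieces, ignore_index=True), pop_type)


def map_correlation(map_a: LinkageMap, map_b: LinkageMap) -> float:
    """Pearson correlation of cumulative cM at shared physical positions.

    The coarser map's marker positions are the comparison points; in the
    finer map the cumulative position of the last marker at or before
    each point is used (interpolation-free). Pooled over chromosomes.
    """
    # the map with fewer markers defines the comparison grid
    coarse, fine = ((map_a, map_b) if len(map_a.table) <= len(map_b.table)
                    else (map_b, map_a))
    xs, ys = [], []
    for chrom in dict.fromkeys(coarse.table["chrom"]):
        ct = coarse.chrom_table(chrom)
        ft = fine.chrom_table(chrom)
        if ft.empty:
            continue
        fpos = ft["pos"].to_numpy()
        fcm = ft["cm"].to_numpy()
        idx = np.searchsorted(fpos, ct["pos"].to_numpy(), side="right") - 1
        ok = idx >= 0
        xs.append(ct["cm"].to_numpy()[ok])
        ys.append(fcm[idx[ok]])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise ValueError("fewer than 3 shared positions between maps")
    return float(np.corrcoef(x, y)[0, 1])
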