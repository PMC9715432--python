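"""Reading, validating and summarising per-CpG bisulfite count data.

Internal convention: 0-based half-open coordinates; a CpG site is recorded at
the plus-strand cytosine position.  Bismark ``.cov`` files (1-based inclusive
single-base records, ``chrom  start  end  pct  count_meth  count_unmeth``)
are converted at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError

COV_COLUMNS = ["chrom", "pos", "count_meth", "count_unmeth"]


class BismarkParseError(ValueError):
    """Malformed Bismark coverage input; message names offending lines."""


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def sort_chrom_names(names) -> list[str]:
    """Natural-order chromosome names (chr2 before chr10)."""
    return sorted(set(names), key=_natural_key)


# ---------------------------------------------------------------------------
# Bismark coverage I/O


def read_bismark_cov(path) -> pd.DataFrame:
    """Read a Bismark coverage file into a 0-based per-site count table.

    Returns a DataFrame with columns ``chrom, pos, count_meth, count_unmeth``
    sorted by chromosome (natural order) and position.  The percentage column
    is recomputed from the counts and must agree within 0.5 percentage
    points.  Multi-base records (``end != start``) and non-numeric counts are
    reported with their 1-based line numbers.
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment=None, dtype=str,
            names=["chrom", "start", "end", "pct", "count_meth", "count_unmeth"],
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=COV_COLUMNS)
    if raw.shape[1] != 6:
        raise BismarkParseError(f"{path}: expected 6 tab-separated columns")

    numeric = {}
    bad = np.zeros(len(raw), dtype=bool)
    for col in ("start", "end", "pct", "count_meth", "count_unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad |= vals.isna().to_numpy()
        numeric[col] = vals
    if bad.any():
        lines = (np.flatnonzero(bad) + 1)[:10].tolist()
        raise BismarkParseError(f"{path}: non-numeric fields on line(s) {lines}")

    start = numeric["start"].astype(np.int64)
    end = numeric["end"].astype(np.int64)
    multi = (end != start).to_numpy()
    if multi.any():
        lines = (np.flatnonzero(multi) + 1)[:10].tolist()
        raise BismarkParseError(
            f"{path}: multi-base records (end != start) on line(s) {lines}"
        )

    meth = numeric["count_meth"].astype(np.int64)
    unmeth = numeric["count_unmeth"].astype(np.int64)
    if (meth < 0).any() or (unmeth < 0).any():
        raise BismarkParseError(f"{path}: negative counts")
    total = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * meth / total, 0.0)
    mismatch = (np.abs(pct - numeric["pct"].to_numpy()) > 0.5) & (total.to_numpy() > 0)
    if mismatch.any():
        lines = (np.flatnonzero(mismatch) + 1)[:10].tolist()
        raise BismarkParseError(
            f"{path}: stated %methylation disagrees with counts on line(s) {lines}"
        )

    df = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "pos": start - 1,  # 1-based inclusive -> 0-based
            "count_meth": meth,
            "count_unmeth": unmeth,
        }
    )
    order = sort_chrom_names(df["chrom"])
    df["chrom"] = pd.Categorical(df["chrom"], categories=order, ordered=True)
    df = df.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bismark_cov(table: pd.DataFrame, path) -> None:
    """Write a 0-based count table as a Bismark coverage file."""
    total = table["count_meth"] + table["count_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * table["count_meth"] / total, 0.0)
    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "start": table["pos"] + 1,
            "end": table["pos"] + 1,
            "pct": pct,
            "count_meth": table["count_meth"],
            "count_unmeth": table["count_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def collapse_strands(table: pd.DataFrame) -> pd.DataFrame:
    """Merge minus-strand records at ``pos+1`` into the plus-strand record.

    Greedy left-to-right within each chromosome: a record at position p+1 is
    summed into an existing record at p; chains (p, p+1, p+2) collapse the
    middle record into p and keep p+2 separate.
    """
    parts = []
    for chrom, sub in table.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        meth = sub["count_meth"].to_numpy().copy()
        unmeth = sub["count_unmeth"].to_numpy().copy()
        keep = np.ones(pos.size, dtype=bool)
        i = 0
        while i + 1 < pos.size:
            if pos[i + 1] == pos[i] + 1:
                meth[i] += meth[i + 1]
                unmeth[i] += unmeth[i + 1]
                keep[i + 1] = False
                i += 2
            else:
                i += 1
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "count_meth": meth[keep],
                    "count_unmeth": unmeth[keep],
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=COV_COLUMNS)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Multi-sample matrix


@dataclass
class MethylomeMatrix:
    """Shared CpG site list with per-sample methylated/total read counts.

    ``meth`` and ``total`` are (n_sites, n_samples) integer arrays; a total
    of zero marks a missing (or coverage-masked) observation.  ``sites`` has
    columns ``chrom`` and ``pos``, strictly increasing within chromosome.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]
    populations: dict[str, str]

    def __post_init__(self) -> None:
        if self.meth.shape != self.total.shape:
            raise ValueError("meth/total shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count arrays do not match sites x samples")
        if np.any(self.meth > self.total) or np.any(self.meth < 0):
            raise ValueError("count_meth must lie in [0, total]")
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (np.diff(pos) <= 0)):
            raise ValueError("site coordinates must strictly increase within chromosome")

    # -- basic views --------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def population_of(self, sample: str) -> str:
        return self.populations[sample]

    def samples_of(self, population: str) -> list[str]:
        return [s for s in self.samples if self.populations[s] == population]

    def group_columns(self, population: str) -> np.ndarray:
        cols = [i for i, s in enumerate(self.samples)
                if self.populations[s] == population]
        if not cols:
            raise KeyError(f"no samples for population {population!r}")
        return np.asarray(cols)

    def levels(self) -> np.ndarray:
        """Per-site, per-sample mCG/CG; NaN where coverage is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.meth / self.total
        return np.where(self.total > 0, lv, np.nan)

    def chrom_slices(self) -> dict[str, slice]:
        chrom = self.sites["chrom"].to_numpy()
        out, start = {}, 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                out[chrom[start]] = slice(start, i)
                start = i
        return out

    def subset_sites(self, mask) -> "MethylomeMatrix":
        mask = np.asarray(mask)
        return MethylomeMatrix(
            self.sites.iloc[mask].reset_index(drop=True),
            self.meth[mask], self.total[mask],
            list(self.samples), dict(self.populations),
        )

    def sample_table(self, sample: str) -> pd.DataFrame:
        j = self.sample_index(sample)
        covered = self.total[:, j] > 0
        return pd.DataFrame(
            {
                "chrom": self.sites["chrom"].to_numpy()[covered],
                "pos": self.sites["pos"].to_numpy()[covered],
                "count_meth": self.meth[covered, j],
                "count_unmeth": self.total[covered, j] - self.meth[covered, j],
            }
        )

    # -- construction -------------------------------------------------------
    @classmethod
    def from_tables(cls, tables: dict[str, pd.DataFrame],
                    populations: dict[str, str]) -> "MethylomeMatrix":
        """Outer-join per-sample count tables on (chrom, pos)."""
        samples = list(tables)
        missing = [s for s in samples if s not in populations]
        if missing:
            raise ValueError(f"samples without population label: {missing}")
        keys = pd.concat(
            [t[["chrom", "pos"]] for t in tables.values()], ignore_index=True
        ).drop_duplicates()
        order = sort_chrom_names(keys["chrom"])
        keys["chrom"] = pd.Categorical(keys["chrom"], categories=order, ordered=True)
        keys = keys.sort_values(["chrom", "pos"], ignore_index=True)
        keys["chrom"] = keys["chrom"].astype(str)
        index = pd.MultiIndex.from_frame(keys)
        meth = np.zeros((len(keys), len(samples)), dtype=np.int64)
        total = np.zeros_like(meth)
        for j, s in enumerate(samples):
            t = tables[s].set_index(["chrom", "pos"])
            t = t.reindex(index, fill_value=0)
            meth[:, j] = t["count_meth"].to_numpy()
            total[:, j] = meth[:, j] + t["count_unmeth"].to_numpy()
        return cls(keys, meth, total, samples, dict(populations))


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample_id, population, path."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "population", "path"}
    if not needed.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(needed)}")
    return df


def load_cohort(sheet_path) -> MethylomeMatrix:
    import os

    sheet = read_sample_sheet(sheet_path)
    base = os.path.dirname(os.fspath(sheet_path))
    tables, pops = {}, {}
    for row in sheet.itertuples():
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        tables[row.sample_id] = read_bismark_cov(p)
        pops[row.sample_id] = row.population
    return MethylomeMatrix.from_tables(tables, pops)


# ---------------------------------------------------------------------------
# Filtering and summaries


def filter_coverage(matrix: MethylomeMatrix, min_cov: int = 4,
                    max_cov: int = 100) -> MethylomeMatrix:
    """Mask per-sample observations with coverage outside [min_cov, max_cov].

    Masking zeroes the counts, so a masked observation is indistinguishable
    from a missing one downstream.  Idempotent.
    """
    if min_cov > max_cov:
        raise ConfigError(f"min_cov ({min_cov}) > max_cov ({max_cov})")
    bad = (matrix.total < min_cov) | (matrix.total > max_cov)
    meth = np.where(bad, 0, matrix.meth)
    total = np.where(bad, 0, matrix.total)
    return MethylomeMatrix(matrix.sites.copy(), meth, total,
                           list(matrix.samples), dict(matrix.populations))


def group_complete_mask(matrix: MethylomeMatrix, populations) -> np.ndarray:
    """Sites covered (total > 0) in every sample of every listed population."""
    mask = np.ones(matrix.n_sites, dtype=bool)
    for pop in populations:
        cols = matrix.group_columns(pop)
        mask &= (matrix.total[:, cols] > 0).all(axis=1)
    return mask


def window_means(chroms, pos, values, window: int,
                 chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Unweighted mean of site-level values in non-overlapping windows.

    NaN values (uncovered sites) are ignored; windows without any covered
    site are omitted.  Returns a bedGraph-style frame.
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    chroms = np.asarray(chroms)
    pos = np.asarray(pos)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    parts = []
    df = pd.DataFrame({"chrom": chroms[ok], "win": pos[ok] // window, "v": values[ok]})
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    g = df.groupby(["chrom", "win"], sort=True, observed=True)["v"].mean().reset_index()
    g["start"] = g["win"] * window
    g["end"] = g["start"] + window
    if chrom_sizes is not None:
        g["end"] = np.minimum(g["end"], g["chrom"].map(chrom_sizes))
    return g[["chrom", "start", "end", "v"]].rename(columns={"v": "value"})


def sample_window_track(matrix: MethylomeMatrix, sample: str, window: int = 50,
                        chrom_sizes=None) -> pd.DataFrame:
    j = matrix.sample_index(sample)
    return window_means(
        matrix.sites["chrom"], matrix.sites["pos"], matrix.levels()[:, j],
        window, chrom_sizes,
    )


def population_window_track(matrix: MethylomeMatrix, population: str,
                            window: int = 50, chrom_sizes=None) -> pd.DataFrame:
    """Window track of population-averaged site levels (mean over covered samples)."""
    cols = matrix.group_columns(population)
    with np.errstate(invalid="ignore"):
        site_mean = np.nanmean(matrix.levels()[:, cols], axis=1)
    return window_means(
        matrix.sites["chrom"], matrix.sites["pos"], site_mean, window, chrom_sizes
    )


def conversion_rate(spike_in: pd.DataFrame) -> float:
    """Bisulfite conversion rate from a fully unmethylated spike-in.

    ``1 - sum(count_meth) / sum(coverage)`` over all control cytosines.
    """
    meth = int(spike_in["count_meth"].sum())
    total = meth + int(spike_in["count_unmeth"].sum())
    if total == 0:
        raise ValueError("conversion rate undefined: zero total spike-in coverage")
    return 1.0 - meth / total
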