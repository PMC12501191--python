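"""Product profiles from replicate peak-area tables.

Converts long-format GC-MS peak-area tables (enzyme, replicate, analyte,
area) into relative product-abundance compositions per replicate, replicate
mean +/- SD summaries, activity flags, and logged total-activity measures.

Compositions are defined trace-internally: each replicate's analyte areas
are divided by their own sum.  The internal standard is used only for the
detection threshold (a replicate whose total analyte area falls below a
configurable fraction of the internal-standard area is called inactive)
and never enters the composition itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

#: Reserved analyte name for the internal standard column.
INTERNAL_STANDARD = "IS"

#: Default controlled product vocabulary (diterpene olefins and alcohols);
#: open-ended — tables may introduce further analytes.
DEFAULT_VOCABULARY = (
    "levopimaradiene",
    "abietadiene",
    "13-OH-abietene",
    "isopimaradiene",
    "sandaracopimaradiene",
    "isopimara-8,15-diene",
    "pimaradiene",
    "pimara-9(11),15-diene",
)


@dataclass
class PeakTable:
    """Long-format peak areas with one internal-standard row per replicate."""

    data: pd.DataFrame  # columns: enzyme, replicate, analyte, area
    internal_standard: str = INTERNAL_STANDARD

    def __post_init__(self):
        required = {"enzyme", "replicate", "analyte", "area"}
        missing = required - set(self.data.columns)
        if missing:
            raise InputError(f"peak table missing columns: {sorted(missing)}")
        df = self.data.copy()
        df["area"] = pd.to_numeric(df["area"])
        if (df["area"] < 0).any():
            bad = df.loc[df["area"] < 0].iloc[0]
            raise InputError(f"negative peak area for {bad['enzyme']}/"
                             f"{bad['replicate']}/{bad['analyte']}")
        is_rows = df[df["analyte"] == self.internal_standard]
        reps = df[["enzyme", "replicate"]].drop_duplicates()
        have = is_rows[["enzyme", "replicate"]].drop_duplicates()
        merged = reps.merge(have, how="left", indicator=True)
        if (merged["_merge"] == "left_only").any():
            bad = merged.loc[merged["_merge"] == "left_only"].iloc[0]
            raise InputError(f"replicate {bad['enzyme']}/{bad['replicate']} "
                             f"lacks an internal-standard row")
        if (is_rows["area"] <= 0).any():
            raise InputError("internal-standard areas must be positive")
        self.data = df

    @classmethod
    def from_csv(cls, path, internal_standard: str = INTERNAL_STANDARD) -> "PeakTable":
        return cls(pd.read_csv(path), internal_standard)

    def enzymes(self) -> list:
        return list(dict.fromkeys(self.data["enzyme"]))

    def subset(self, enzyme) -> "PeakTable":
        return PeakTable(self.data[self.data["enzyme"] == enzyme].copy(),
                         self.internal_standard)


@dataclass
class ReplicateComposition:
    """One replicate's relative product abundances (or an inactive marker)."""

    enzyme: str
    replicate: str
    products: tuple
    fractions: np.ndarray | None  # None when inactive
    total_area: float
    internal_standard_area: float

    @property
    def active(self) -> bool:
        return self.fractions is not None

    def as_dict(self) -> dict:
        if not self.active:
            return {}
        return dict(zip(self.products, self.fractions))


def relative_abundances(table: PeakTable, enzyme=None, vocabulary=None,
                        detection_fraction: float = 1e-3) -> list:
    """Per-replicate compositions: analyte areas over their trace total.

    A replicate is flagged inactive (no composition) when its total analyte
    area is below ``detection_fraction`` of its internal-standard area.
    """
    df = table.data
    if enzyme is not None:
        df = df[df["enzyme"] == enzyme]
        if df.empty:
            raise InputError(f"no rows for enzyme {enzyme!r}")
    analytes = df[df["analyte"] != table.internal_standard]
    if vocabulary is None:
        vocabulary = tuple(dict.fromkeys(analytes["analyte"]))
    else:
        vocabulary = tuple(vocabulary)
        unknown = set(analytes["analyte"]) - set(vocabulary)
        if unknown:
            raise InputError(f"analytes outside the vocabulary: {sorted(unknown)}")
    out = []
    for (enz, rep), grp in df.groupby(["enzyme", "replicate"], sort=False):
        is_area = float(grp.loc[grp["analyte"] == table.internal_standard, "area"].iloc[0])
        prod = grp[grp["analyte"] != table.internal_standard]
        areas = prod.groupby("analyte")["area"].sum()
        vec = np.array([areas.get(p, 0.0) for p in vocabulary], dtype=float)
        total = float(vec.sum())
        if total <= 0 or total < detection_fraction * is_area:
            frac = None
        else:
            frac = vec / total
        out.append(ReplicateComposition(enz, rep, vocabulary, frac, total, is_area))
    return out


@dataclass
class ProductProfile:
    """Replicate-summarised composition over a product vocabulary.

    ``mean`` is the renormalised arithmetic mean of the active replicate
    compositions (itself a composition); ``sd`` is the per-product sample
    standard deviation (n-1 denominator) of the raw replicate fractions.
    An inactive profile (no active replicates) carries an all-zero mean.
    """

    enzyme: str
    products: tuple
    mean: np.ndarray
    sd: np.ndarray
    n: int
    active: bool
    under_replicated: bool = False

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.sd = np.asarray(self.sd, float)
        if self.active:
            if not np.isclose(self.mean.sum(), 1.0, atol=1e-9):
                raise InputError("active profile mean must sum to 1")
            if np.any(self.mean < -1e-12) or np.any(self.mean > 1 + 1e-12):
                raise InputError("profile fractions must lie in [0, 1]")
        if np.any(self.sd < 0):
            raise InputError("SD must be nonnegative")

    def as_dict(self) -> dict:
        if not self.active:
            return {}
        return dict(zip(self.products, self.mean))

    def fraction(self, product: str) -> float:
        if product not in self.products:
            return 0.0
        return float(self.mean[self.products.index(product)])

    def sd_of(self, product: str) -> float:
        if product not in self.products:
            return 0.0
        return float(self.sd[self.products.index(product)])

    @classmethod
    def pure(cls, product: str, enzyme: str = "reference") -> "ProductProfile":
        """A single-product reference profile (e.g. 100% isopimaradiene)."""
        return cls(enzyme, (product,), np.array([1.0]), np.array([0.0]),
                   n=1, active=True, under_replicated=False)


def replicate_summary(compositions, n_min: int = 3,
                      enzyme: str | None = None) -> ProductProfile:
    """Summarise replicate compositions into a ProductProfile.

    Fewer than ``n_min`` active replicates flags the profile as
    under-replicated (a warning-level flag, not an error); zero active
    replicates yields an inactive profile.
    """
    comps = list(compositions)
    if not comps:
        raise InputError("no replicate compositions supplied")
    if enzyme is None:
        enzyme = comps[0].enzyme
    active = [c for c in comps if c.active]
    vocab = tuple(dict.fromkeys(p for c in comps for p in c.products))
    if not active:
        z = np.zeros(len(vocab))
        return ProductProfile(enzyme, vocab, z, z.copy(), n=0, active=False,
                              under_replicated=True)
    mat = np.zeros((len(active), len(vocab)))
    for i, c in enumerate(active):
        d = c.as_dict()
        mat[i] = [d.get(p, 0.0) for p in vocab]
    mean = mat.mean(axis=0)
    mean = mean / mean.sum()
    sd = mat.std(axis=0, ddof=1) if len(active) > 1 else np.zeros(len(vocab))
    return ProductProfile(enzyme, vocab, mean, sd, n=len(active), active=True,
                          under_replicated=len(active) < n_min)


def profiles_from_table(table: PeakTable, n_min: int = 3, vocabulary=None,
                        detection_fraction: float = 1e-3) -> dict:
    """All enzymes' profiles from one peak table, keyed by enzyme id."""
    out = {}
    for enz in table.enzymes():
        comps = relative_abundances(table, enzyme=enz, vocabulary=vocabulary,
                                    detection_fraction=detection_fraction)
        out[enz] = replicate_summary(comps, n_min=n_min, enzyme=enz)
    return out


def log_total_activity(table: PeakTable, base: float = 10.0,
                       detection_fraction: float = 0.0) -> pd.DataFrame:
    """Logged total analyte area per replicate (a proxy for total activity).

    Returns a frame (enzyme, replicate, total_area, log_total, below_detection);
    replicates at or below the detection threshold get log_total = NaN and the
    below_detection flag rather than -inf.
    """
    comps = relative_abundances(table, detection_fraction=0.0)
    rows = []
    for c in comps:
        below = c.total_area <= 0 or c.total_area < detection_fraction * c.internal_standard_area
        log_total = np.nan if below else np.log(c.total_area) / np.log(base)
        rows.append({"enzyme": c.enzyme, "replicate": c.replicate,
                     "total_area": c.total_area, "log_total": log_total,
                     "below_detection": below})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vocabulary alignment and I/O
# ---------------------------------------------------------------------------

def union_vocabulary(profiles) -> tuple:
    """Name-union vocabulary across profiles (order of first appearance)."""
    return tuple(dict.fromkeys(p for prof in profiles for p in prof.products))


def aligned_compositions(profiles, vocabulary=None) -> tuple:
    """Zero-filled composition matrix over the union vocabulary."""
    profiles = list(profiles)
    if vocabulary is None:
        vocabulary = union_vocabulary(profiles)
    mat = np.zeros((len(profiles), len(vocabulary)))
    for i, prof in enumerate(profiles):
        d = prof.as_dict()
        mat[i] = [d.get(p, 0.0) for p in vocabulary]
    return vocabulary, mat


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Wide table: one row per enzyme, product + sd_<product> columns."""
    profs = list(profiles.values()) if isinstance(profiles, dict) else list(profiles)
    vocab = union_vocabulary(profs)
    rows = []
    for p in profs:
        d = p.as_dict()
        s = dict(zip(p.products, p.sd))
        row = {"enzyme": p.enzyme, "n": p.n, "active": p.active,
               "under_replicated": p.under_replicated}
        for v in vocab:
            row[v] = d.get(v, 0.0)
        for v in vocab:
            row[f"sd_{v}"] = s.get(v, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> dict:
    """Inverse of :func:`profiles_to_frame`."""
    meta = {"enzyme", "n", "active", "under_replicated"}
    vocab = tuple(c for c in df.columns if c not in meta and not c.startswith("sd_"))
    out = {}
    for _, row in df.iterrows():
        mean = np.array([row[v] for v in vocab], float)
        sd = np.array([row.get(f"sd_{v}", 0.0) for v in vocab], float)
        active = bool(row["active"])
        if active and mean.sum() > 0:
            mean = mean / mean.sum()
        out[row["enzyme"]] = ProductProfile(row["enzyme"], vocab, mean, sd,
                                            n=int(row["n"]), active=active,
                                            under_replicated=bool(row["under_replicated"]))
    return out
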