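"""Ripe-versus-unripe class-composition correlations (developmental constraints).

If ripe fruit scent is constrained by the chemistry of the unripe fruit it
develops from, species that invest heavily in a biochemical class when
unripe should keep doing so when ripe — even if the individual compounds
turn over.  This module pairs ripe and unripe class-level profiles by
species, computes a Spearman rank correlation per class, and summarises
overall similarity as a weighted mean correlation (weights = mean ripe-fruit
relative amount per class).  The "unknown" class is excluded: a correlation
between unidentified compounds would be chemically meaningless, and that
class carries well under a few percent of the profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fruitscent.voctable import CLASS_ORDER, SpeciesProfile

KNOWN_CLASSES: tuple[str, ...] = tuple(c for c in CLASS_ORDER if c != "unknown")


@dataclass
class PairedClassProfiles:
    """Ripe and unripe class-level relative amounts for the same species.

    The unknown class is dropped without renormalising, so each row records
    the share of the *full* scent profile carried by the identified classes.
    """

    species: list[str]
    ripe: pd.DataFrame
    unripe: pd.DataFrame
    dropped_species: list[str] = field(default_factory=list)
    unknown_mean_share: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.ripe.index) != self.species or list(self.unripe.index) != self.species:
            raise ValueError("ripe and unripe matrices must share the species order")
        if list(self.ripe.columns) != list(self.unripe.columns):
            raise ValueError("ripe and unripe matrices must share columns")


@dataclass
class DevCorrResult:
    """Per-class Spearman correlations between ripe and unripe compositions."""

    classes: list[str]
    rho: pd.Series               # NaN where undefined (constant class)
    p: pd.Series
    weights: pd.Series           # mean ripe relative amount per class
    weighted_mean_rho: float
    n_species: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho": self.rho, "p": self.p, "weight": self.weights})


def pair_ripe_unripe(
    ripe: SpeciesProfile, unripe: SpeciesProfile
) -> PairedClassProfiles:
    """Align class-level ripe and unripe profiles on their shared species.

    Species present in only one stage are listed in ``dropped_species``.
    The mean share of the unknown class (before exclusion) is reported per
    stage so its negligibility can be checked rather than assumed.
    """
    if ripe.level != "class" or unripe.level != "class":
        raise ValueError("pair_ripe_unripe expects class-level profiles")
    shared = sorted(set(ripe.species) & set(unripe.species))
    if not shared:
        raise ValueError("no species shared between ripe and unripe profiles")
    dropped = sorted(set(ripe.species) ^ set(unripe.species))

    def _prep(prof: SpeciesProfile) -> tuple[pd.DataFrame, float]:
        df = prof.values.loc[shared]
        unknown = float(df["unknown"].mean()) if "unknown" in df.columns else 0.0
        kept = [c for c in KNOWN_CLASSES if c in df.columns]
        return df[kept], unknown

    ripe_df, unk_r = _prep(ripe)
    unripe_df, unk_u = _prep(unripe)
    cols = sorted(set(ripe_df.columns) | set(unripe_df.columns),
                  key=KNOWN_CLASSES.index)
    ripe_df = ripe_df.reindex(columns=cols, fill_value=0.0)
    unripe_df = unripe_df.reindex(columns=cols, fill_value=0.0)
    return PairedClassProfiles(
        shared, ripe_df, unripe_df, dropped_species=dropped,
        unknown_mean_share={"ripe": unk_r, "unripe": unk_u},
    )


def spearman_by_class(
    paired: PairedClassProfiles, method: str = "t-approximation"
) -> DevCorrResult:
    """Spearman's rho between ripe and unripe relative amounts, per class.

    Midranks handle ties; the two-sided test of rho = 0 uses the t
    approximation by default, or an exact/permutation reference distribution
    (``method="exact"``) for small species counts.  A class constant in both
    stages has no rank variation: its rho is reported as NaN and it drops out
    of the weighted mean.
    """
    n = len(paired.species)
    if n < 3:
        raise ValueError(f"need >= 3 paired species, got {n}")
    if method not in {"t-approximation", "exact"}:
        raise ValueError("method must be 't-approximation' or 'exact'")
    rhos, ps = {}, {}
    for cls in paired.ripe.columns:
        x = paired.unripe[cls].to_numpy()
        y = paired.ripe[cls].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            rhos[cls], ps[cls] = np.nan, np.nan
            continue
        if method == "exact":
            res = stats.permutation_test(
                (x, y),
                lambda a, b: stats.spearmanr(a, b).statistic,
                permutation_type="pairings",
                n_resamples=9999,
                alternative="two-sided",
                rng=np.random.default_rng(0),
            )
            rhos[cls] = float(stats.spearmanr(x, y).statistic)
            ps[cls] = float(res.pvalue)
        else:
            rho, p = stats.spearmanr(x, y)
            rhos[cls], ps[cls] = float(rho), float(p)
    classes = list(paired.ripe.columns)
    rho = pd.Series(rhos, index=classes, name="rho")
    p = pd.Series(ps, index=classes, name="p")
    weights = paired.ripe.mean(axis=0).rename("weight")
    result = DevCorrResult(classes, rho, p, weights, np.nan, n_species=n)
    result.weighted_mean_rho = weighted_mean_rho(result)
    return result


def weighted_mean_rho(result: DevCorrResult, normalize: bool = True) -> float:
    """Mean per-class rho weighted by the class's share of ripe fruit scent.

    Classes with undefined rho are excluded from numerator and denominator.
    With ``normalize`` (default) the weights are divided by their own sum,
    making this a true weighted mean even though the raw ripe shares sum to
    slightly under 1 once the unknown class is excluded.
    """
    defined = result.rho.notna()
    if not defined.any():
        raise ValueError("no class has a defined correlation")
    w = result.weights[defined]
    r = result.rho[defined]
    if normalize:
        if float(w.sum()) == 0:
            raise ValueError("all weights are zero")
        return float((w * r).sum() / w.sum())
    return float((w * r).sum())
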