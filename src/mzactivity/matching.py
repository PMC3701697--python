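"""Tentative matching of m/z features to metabolites via adducts/isotopologues.

An observed feature carries only (m/z, retention time); a neutral metabolite
of monoisotopic mass M can appear as many ionized derivative forms (M+H[1+],
M+Na[1+], the C13 isotopologue M(C13)+H[1+], ...).  Matching therefore
produces a *many-to-many* map between features and (metabolite, form)
pairs, within a relative mass tolerance in parts per million:

    |mz_obs - mz_theo| / mz_theo * 1e6  <=  ppm_tol

The ambiguity of this map is deliberate; it is resolved downstream by the
network statistics, not here.  Retention time is carried as metadata but
never used for matching.

The derivative tables below are explicit, user-replaceable defaults; the
electron mass is folded into the proton shift constant (1.00728 Da), and the
C12->C13 substitution adds 1.00336 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_io import MetabolicModel

__all__ = [
    "MzFeature",
    "FeatureTable",
    "DerivativeRule",
    "MatchRecord",
    "MatchMap",
    "PROTON",
    "C13_SHIFT",
    "build_derivative_table",
    "compute_derivative_mz",
    "match_features",
    "TheoreticalIndex",
]

PROTON = 1.00728   # proton mass with electron correction folded in, Da
C13_SHIFT = 1.00336  # mass difference of one C13 substitution, Da


@dataclass(frozen=True)
class MzFeature:
    feature_id: str
    mz: float                      # observed mass-to-charge, Da
    rtime: float = 0.0             # retention time, s (metadata only)
    p_value: float | None = None
    statistic: float | None = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id!r}: mz must be > 0")


class FeatureTable:
    """An ordered list of m/z features, tagged as reference or significant."""

    def __init__(self, features: Sequence[MzFeature], role: str = "reference"):
        self.features = list(features)
        self.role = role
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in table")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i: int) -> MzFeature:
        return self.features[i]

    @property
    def mz(self) -> np.ndarray:
        return np.array([f.mz for f in self.features])

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def subset(self, indices: Iterable[int], role: str = "significant") -> "FeatureTable":
        return FeatureTable([self.features[i] for i in indices], role=role)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, role: str = "reference") -> "FeatureTable":
        if "mz" not in df.columns:
            raise ValueError("feature table requires an 'mz' column")
        ids = (
            df["feature_id"].astype(str).tolist()
            if "feature_id" in df.columns
            else [f"F{i:05d}" for i in range(len(df))]
        )
        feats = []
        for fid, (_, row) in zip(ids, df.iterrows()):
            feats.append(
                MzFeature(
                    feature_id=fid,
                    mz=float(row["mz"]),
                    rtime=float(row.get("rtime", 0.0) or 0.0),
                    p_value=(float(row["p_value"]) if "p_value" in df.columns and pd.notna(row["p_value"]) else None),
                    statistic=(float(row["statistic"]) if "statistic" in df.columns and pd.notna(row["statistic"]) else None),
                )
            )
        return cls(feats, role=role)

    @classmethod
    def from_tsv(cls, path: str | Path, role: str = "reference") -> "FeatureTable":
        """Read a tab-delimited table with header columns mz, rtime, p_value, statistic."""
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), role=role)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "mz": [f.mz for f in self.features],
                "rtime": [f.rtime for f in self.features],
                "p_value": [f.p_value for f in self.features],
                "statistic": [f.statistic for f in self.features],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DerivativeRule:
    """One adduct/isotopologue form: observed m/z = (M + mass_shift) / charge."""

    form_name: str
    mass_shift: float            # Da added to the neutral monoisotopic mass
    charge: int = 1
    mode: str = "positive"
    is_primary: bool = False
    c13_of_primary: bool = False  # the C13 partner of the primary ion

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


_POSITIVE_RULES = (
    DerivativeRule("M+H[1+]", PROTON, 1, "positive", is_primary=True),
    DerivativeRule("M(C13)+H[1+]", PROTON + C13_SHIFT, 1, "positive", c13_of_primary=True),
    DerivativeRule("M+Na[1+]", 22.98922, 1, "positive"),
    DerivativeRule("M+K[1+]", 38.96316, 1, "positive"),
    DerivativeRule("M+NH4[1+]", 18.03383, 1, "positive"),
    DerivativeRule("M+H-H2O[1+]", -17.00329, 1, "positive"),
    DerivativeRule("M+2H[2+]", 2 * PROTON, 2, "positive"),
    DerivativeRule("M+ACN+H[1+]", 42.03383, 1, "positive"),
)

_NEGATIVE_RULES = (
    DerivativeRule("M-H[-]", -PROTON, 1, "negative", is_primary=True),
    DerivativeRule("M(C13)-H[-]", -PROTON + C13_SHIFT, 1, "negative", c13_of_primary=True),
    DerivativeRule("M+Cl[-]", 34.96940, 1, "negative"),
    DerivativeRule("M-H2O-H[-]", -19.01839, 1, "negative"),
    DerivativeRule("M+formate[-]", 44.99820, 1, "negative"),
)


def build_derivative_table(mode: str) -> list[DerivativeRule]:
    """Default derivative-form table for an ion mode.

    Exactly one rule per mode is the primary ion: M+H[1+] in positive mode,
    M-H[-] in negative mode.  User-supplied tables may replace the default.
    """
    if mode == "positive":
        return list(_POSITIVE_RULES)
    if mode == "negative":
        return list(_NEGATIVE_RULES)
    raise ValueError(f"unknown ion mode {mode!r}; expected 'positive' or 'negative'")


def compute_derivative_mz(mono_mass: float, rule: DerivativeRule) -> float:
    """Theoretical m/z of one derivative form of a neutral mass."""
    if not mono_mass > 0:
        raise ValueError("mono_mass must be > 0")
    return (mono_mass + rule.mass_shift) / rule.charge


@dataclass(frozen=True)
class MatchRecord:
    feature_id: str
    metabolite_id: str
    form_name: str
    theoretical_mz: float
    ppm_error: float


class MatchMap:
    """The many-to-many feature <-> (metabolite, form) relation."""

    def __init__(self, records: Sequence[MatchRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def metabolites(self) -> set[str]:
        return {r.metabolite_id for r in self.records}

    @property
    def features(self) -> set[str]:
        return {r.feature_id for r in self.records}

    def by_feature(self) -> dict[str, list[MatchRecord]]:
        out: dict[str, list[MatchRecord]] = {}
        for r in self.records:
            out.setdefault(r.feature_id, []).append(r)
        return out

    def by_metabolite(self) -> dict[str, list[MatchRecord]]:
        out: dict[str, list[MatchRecord]] = {}
        for r in self.records:
            out.setdefault(r.metabolite_id, []).append(r)
        return out

    def forms_of(self, metabolite_id: str) -> dict[str, list[str]]:
        """form_name -> supporting feature ids, for one metabolite."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            if r.metabolite_id == metabolite_id:
                out.setdefault(r.form_name, []).append(r.feature_id)
        return out

    def features_of(self, metabolite_ids: Iterable[str]) -> set[str]:
        wanted = set(metabolite_ids)
        return {r.feature_id for r in self.records if r.metabolite_id in wanted}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "metabolite_id": r.metabolite_id,
                    "form": r.form_name,
                    "theoretical_mz": r.theoretical_mz,
                    "ppm_error": r.ppm_error,
                }
                for r in self.records
            ],
            columns=["feature_id", "metabolite_id", "form", "theoretical_mz", "ppm_error"],
        )


class TheoreticalIndex:
    """Sorted index of all theoretical derivative m/z of a model.

    Built once per (model, rule table) and reused across permutations; lookup
    per observed m/z is a binary search over the sorted theoretical values.
    """

    def __init__(self, model: MetabolicModel, rules: Sequence[DerivativeRule]):
        self.rules = list(rules)
        met_ids: list[str] = []
        forms: list[str] = []
        mzs: list[float] = []
        for met in model.metabolites.values():
            if not met.matchable:
                continue
            for rule in self.rules:
                met_ids.append(met.id)
                forms.append(rule.form_name)
                mzs.append(compute_derivative_mz(met.mono_mass, rule))
        order = np.argsort(mzs, kind="stable")
        self.mz = np.asarray(mzs)[order]
        self.metabolite_ids = np.asarray(met_ids, dtype=object)[order]
        self.form_names = np.asarray(forms, dtype=object)[order]
        self._primary_forms = {r.form_name for r in self.rules if r.is_primary}

    def lookup(self, observed: np.ndarray, feature_ids: Sequence[str], ppm_tol: float) -> list[MatchRecord]:
        observed = np.asarray(observed, dtype=float)
        tol = ppm_tol * 1e-6
        # |obs - theo| <= tol * theo  <=>  theo in [obs/(1+tol), obs/(1-tol)]
        lo = np.searchsorted(self.mz, observed / (1.0 + tol), side="left")
        hi = np.searchsorted(self.mz, observed / (1.0 - tol), side="right")
        records = []
        for i, fid in enumerate(feature_ids):
            for j in range(lo[i], hi[i]):
                theo = self.mz[j]
                ppm = abs(observed[i] - theo) / theo * 1e6
                if ppm <= ppm_tol:
                    records.append(
                        MatchRecord(fid, self.metabolite_ids[j], self.form_names[j], theo, ppm)
                    )
        return records

    def primary_supported(self, observed: np.ndarray, ppm_tol: float) -> set[str]:
        """Metabolites whose primary-ion form matches at least one observed m/z."""
        recs = self.lookup(observed, ["_"] * len(observed), ppm_tol)
        return {r.metabolite_id for r in recs if r.form_name in self._primary_forms}


def match_features(
    features: FeatureTable,
    model: MetabolicModel,
    mode: str = "positive",
    ppm_tol: float = 10.0,
    enforce_primary: bool = False,
    reference: FeatureTable | None = None,
    rules: Sequence[DerivativeRule] | None = None,
    index: TheoreticalIndex | None = None,
) -> MatchMap:
    """Compute all tentative (metabolite, form) matches for each feature.

    With ``enforce_primary``, metabolites whose primary-ion form matches no
    feature in the reference list are dropped entirely (the "-z" behaviour);
    the reference defaults to ``features`` itself.  Unmatched features are
    simply absent from the map — they remain in the table and still take
    part in permutation draws.
    """
    if index is None:
        index = TheoreticalIndex(model, rules if rules is not None else build_derivative_table(mode))
    if len(features) == 0:
        return MatchMap([])
    records = index.lookup(features.mz, features.feature_ids, ppm_tol)
    if enforce_primary:
        ref = reference if reference is not None else features
        supported = index.primary_supported(ref.mz, ppm_tol)
        records = [r for r in records if r.metabolite_id in supported]
    return MatchMap(records)
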