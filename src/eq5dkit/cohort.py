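"""Respondent records, a latent-severity cohort simulator, and the
pinned 250-respondent reference cohort.

Two generators are provided:

:func:`sample_cohort`
    Draws respondents from a :class:`CohortSpec`: per-group dimension
    level probabilities are realised by thresholding Gaussian latents
    that share a common severity factor (a Gaussian-copula
    construction), so the marginals are preserved for any association
    strength ``rho`` and the dimensions are independent at ``rho = 0``.

:func:`fixture_cohort`
    Returns a deterministic 250-respondent cohort (133 HIV-positive,
    117 HIV-negative) whose demographic category counts and health-state
    grade counts reproduce the published study margins exactly.  The
    published per-dimension level margins and the published grade
    margins are jointly infeasible under the grading rules (see
    :data:`_FIXTURE_STATES`), so the dimension margins are reproduced at
    the minimum possible total cell deviation, with the anxiety/
    depression dimension and both pain/discomfort margins exact.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import norm

from eq5dkit.tariff import DIMENSIONS, HealthState

__all__ = [
    "GROUPS",
    "VOCABULARIES",
    "CohortError",
    "Respondent",
    "CohortSpec",
    "study_cohort_spec",
    "sample_cohort",
    "fixture_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]

GROUPS: tuple[str, ...] = ("hiv_positive", "hiv_negative")

#: Closed category vocabularies for every categorical respondent field.
VOCABULARIES: Mapping[str, tuple[str, ...]] = {
    "group": GROUPS,
    "age_band": ("18-35", "35-53"),
    "education": ("illiterate", "primary_junior"),
    "occupation": ("farmer", "migrant_worker"),
    "income_band": ("lt8000", "ge8000"),
    "prenatal_visits_band": ("le2", "3", "4", "ge5"),
    "family_size_band": ("3", "4-5", "ge6"),
    "insured": ("true", "false"),
}

#: Demographic fields in schema order (excludes group / id / state).
DEMOGRAPHIC_FIELDS: tuple[str, ...] = (
    "age_band",
    "education",
    "occupation",
    "income_band",
    "prenatal_visits_band",
    "family_size_band",
    "insured",
)

CSV_COLUMNS: tuple[str, ...] = (
    "id",
    "group",
    "age_years",
    "age_band",
    "education",
    "occupation",
    "income_band",
    "prenatal_visits_band",
    "family_size_band",
    "insured",
    "state",
)

# age 35 belongs to the upper band
AGE_RANGES = {"18-35": (18, 34), "35-53": (35, 53)}


class CohortError(ValueError):
    """Raised for invalid cohort specifications or records."""


@dataclass(frozen=True)
class Respondent:
    """One survey record: group membership, demographics and health state."""

    id: str
    group: str
    age_years: int
    age_band: str
    education: str
    occupation: str
    income_band: str
    prenatal_visits_band: str
    family_size_band: str
    insured: bool
    state: HealthState

    def __post_init__(self) -> None:
        for fld in ("group", "education", "occupation", "income_band",
                    "prenatal_visits_band", "family_size_band", "age_band"):
            value = getattr(self, fld)
            if value not in VOCABULARIES[fld]:
                raise CohortError(f"{fld}={value!r} not in {VOCABULARIES[fld]}")
        lo, hi = AGE_RANGES[self.age_band]
        if not (lo <= self.age_years <= hi):
            raise CohortError(
                f"age_years={self.age_years} inconsistent with age_band={self.age_band!r}"
            )


def _band_for_age(age: int) -> str:
    return "35-53" if age >= 35 else "18-35"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``dimension_probs[group][dim]`` is the (p1, p2, p3) level
    distribution of one EQ-5D dimension; ``demographic_probs[group][f]``
    maps each category of demographic field ``f`` to its probability.
    ``rho`` in [0, 1) is the share of latent-severity variance common to
    the five dimensions (0 = independent dimensions).
    """

    n_per_group: Mapping[str, int]
    dimension_probs: Mapping[str, Mapping[str, tuple[float, float, float]]]
    demographic_probs: Mapping[str, Mapping[str, Mapping[str, float]]]
    rho: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise CohortError(f"rho must be in [0, 1), got {self.rho}")
        for group, n in self.n_per_group.items():
            if group not in GROUPS:
                raise CohortError(f"unknown group {group!r}")
            if n < 1:
                raise CohortError(f"n_per_group[{group!r}] must be >= 1, got {n}")
        for group in self.n_per_group:
            dims = self.dimension_probs.get(group, {})
            for dim in DIMENSIONS:
                probs = dims.get(dim)
                if probs is None or len(probs) != 3:
                    raise CohortError(f"missing level probabilities for {group}/{dim}")
                self._check_probs(f"{group}/{dim}", probs)
            demos = self.demographic_probs.get(group, {})
            for fld in DEMOGRAPHIC_FIELDS:
                cats = demos.get(fld)
                if cats is None:
                    raise CohortError(f"missing demographic probabilities for {group}/{fld}")
                if set(cats) != set(VOCABULARIES[fld]):
                    raise CohortError(
                        f"{group}/{fld} categories {sorted(cats)} != "
                        f"{sorted(VOCABULARIES[fld])}"
                    )
                self._check_probs(f"{group}/{fld}", list(cats.values()))

    @staticmethod
    def _check_probs(label: str, probs: Sequence[float]) -> None:
        arr = np.asarray(probs, dtype=float)
        if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
            raise CohortError(
                f"probabilities for {label} must be non-negative and sum to 1, got {list(arr)}"
            )

    def to_yaml(self, path) -> None:
        doc = {
            "format": "eq5dkit-cohort-spec",
            "version": 1,
            "n_per_group": dict(self.n_per_group),
            "dimension_probs": {
                g: {d: [float(p) for p in probs] for d, probs in dims.items()}
                for g, dims in self.dimension_probs.items()
            },
            "demographic_probs": {
                g: {f: {c: float(p) for c, p in cats.items()} for f, cats in flds.items()}
                for g, flds in self.demographic_probs.items()
            },
            "rho": float(self.rho),
            "seed": int(self.seed),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if doc.get("format") != "eq5dkit-cohort-spec":
            raise CohortError("not an eq5dkit cohort-spec file")
        return cls(
            n_per_group=doc["n_per_group"],
            dimension_probs={
                g: {d: tuple(p) for d, p in dims.items()}
                for g, dims in doc["dimension_probs"].items()
            },
            demographic_probs=doc["demographic_probs"],
            rho=doc.get("rho", 0.4),
            seed=doc.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# Published margins used to parameterise the default spec and the fixture.

_DIMENSION_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "hiv_positive": {
        "mo": (119, 14, 0),
        "sc": (130, 3, 0),
        "ua": (109, 23, 1),
        "pd": (98, 34, 1),
        "ad": (77, 52, 4),
    },
    "hiv_negative": {
        "mo": (107, 9, 1),
        "sc": (115, 2, 0),
        "ua": (104, 11, 2),
        "pd": (91, 24, 2),
        "ad": (90, 22, 5),
    },
}

_DEMOGRAPHIC_COUNTS: dict[str, dict[str, tuple[tuple[str, int], ...]]] = {
    "hiv_positive": {
        "age_band": (("18-35", 86), ("35-53", 47)),
        "education": (("illiterate", 114), ("primary_junior", 19)),
        "occupation": (("farmer", 118), ("migrant_worker", 15)),
        "income_band": (("lt8000", 70), ("ge8000", 63)),
        "prenatal_visits_band": (("le2", 48), ("3", 34), ("4", 20), ("ge5", 31)),
        "family_size_band": (("3", 18), ("4-5", 70), ("ge6", 45)),
        "insured": (("true", 126), ("false", 7)),
    },
    "hiv_negative": {
        "age_band": (("18-35", 95), ("35-53", 22)),
        "education": (("illiterate", 92), ("primary_junior", 25)),
        "occupation": (("farmer", 102), ("migrant_worker", 15)),
        "income_band": (("lt8000", 51), ("ge8000", 66)),
        "prenatal_visits_band": (("le2", 56), ("3", 25), ("4", 16), ("ge5", 20)),
        "family_size_band": (("3", 16), ("4-5", 58), ("ge6", 43)),
        "insured": (("true", 112), ("false", 5)),
    },
}

_GROUP_SIZES = {"hiv_positive": 133, "hiv_negative": 117}

# Pinned joint health states per group.  The published grade margins
# (55/45/33/0 positive, 75/22/19/1 negative) are reproduced exactly.
# No joint assignment can also reproduce every published dimension
# margin: a mild state needs at least one level-2 dimension and a
# moderate state needs either a level-3 dimension or at least four
# level-2 dimensions, so the positive group needs at least
# 45 + 4*(33 - 6) = 153 level-2 entries while its published margins
# supply only 126 (the negative group is short by one).  The multisets
# below attain the minimum achievable total cell deviation; anxiety/
# depression and pain/discomfort margins are exact in both groups.
_FIXTURE_STATES: dict[str, tuple[tuple[str, int], ...]] = {
    "hiv_positive": (
        ("11111", 55),  # full
        ("11112", 31),  # mild
        ("11121", 13),  # mild
        ("11122", 1),   # mild
        ("21222", 17),  # moderate: four level-2 dimensions
        ("12222", 3),   # moderate: four level-2 dimensions
        ("11311", 8),   # moderate: level 3 present
        ("11131", 1),   # moderate: level 3 present
        ("11113", 4),   # moderate: level 3 present
    ),
    "hiv_negative": (
        ("11111", 75),  # full
        ("11112", 10),  # mild
        ("11121", 12),  # mild
        ("21222", 10),  # moderate: four level-2 dimensions
        ("12222", 1),   # moderate: four level-2 dimensions
        ("11311", 1),   # moderate: level 3 present
        ("11131", 2),   # moderate: level 3 present
        ("11113", 5),   # moderate: level 3 present
        ("32322", 1),   # severe: distance 7, no level 1, two level 3s
    ),
}

_FIXTURE_SHUFFLE_SEED = 20220405


def study_cohort_spec(rho: float = 0.4, seed: int = 0) -> CohortSpec:
    """The :class:`CohortSpec` parameterised from the published margins."""
    dim_probs = {}
    demo_probs = {}
    for group, n in _GROUP_SIZES.items():
        dim_probs[group] = {
            dim: tuple(c / n for c in counts)
            for dim, counts in _DIMENSION_COUNTS[group].items()
        }
        demo_probs[group] = {
            fld: {cat: c / n for cat, c in cats}
            for fld, cats in _DEMOGRAPHIC_COUNTS[group].items()
        }
    return CohortSpec(
        n_per_group=dict(_GROUP_SIZES),
        dimension_probs=dim_probs,
        demographic_probs=demo_probs,
        rho=rho,
        seed=seed,
    )


def sample_cohort(spec: CohortSpec) -> list[Respondent]:
    """Draw a synthetic cohort from ``spec``.

    Deterministic given ``spec.seed``.  Dimension levels come from a
    shared-latent threshold construction: each respondent draws one
    common severity factor ``z`` and five idiosyncratic factors, and
    dimension ``d`` takes the level whose Gaussian-quantile bin contains
    ``sqrt(rho) z + sqrt(1-rho) e_d``.  Marginals therefore match the
    spec probabilities for any ``rho``.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[Respondent] = []
    for group in GROUPS:
        if group not in spec.n_per_group:
            continue
        n = int(spec.n_per_group[group])
        prefix = "P" if group == "hiv_positive" else "N"

        z = rng.standard_normal(n)
        levels: dict[str, np.ndarray] = {}
        for dim in DIMENSIONS:
            p1, p2, _p3 = spec.dimension_probs[group][dim]
            e = rng.standard_normal(n)
            u = np.sqrt(spec.rho) * z + np.sqrt(1.0 - spec.rho) * e
            c1 = norm.ppf(p1) if p1 > 0 else -np.inf
            c12 = norm.ppf(min(p1 + p2, 1.0)) if p1 + p2 < 1 else np.inf
            levels[dim] = 1 + (u > c1).astype(int) + (u > c12).astype(int)

        demo: dict[str, np.ndarray] = {}
        for fld in DEMOGRAPHIC_FIELDS:
            cats = VOCABULARIES[fld]
            probs = np.asarray(
                [spec.demographic_probs[group][fld][c] for c in cats], dtype=float
            )
            demo[fld] = rng.choice(len(cats), size=n, p=probs / probs.sum())

        ages = np.empty(n, dtype=int)
        for i in range(n):
            band = VOCABULARIES["age_band"][demo["age_band"][i]]
            lo, hi = AGE_RANGES[band]
            ages[i] = rng.integers(lo, hi + 1)

        for i in range(n):
            out.append(
                Respondent(
                    id=f"{prefix}{i + 1:03d}",
                    group=group,
                    age_years=int(ages[i]),
                    age_band=VOCABULARIES["age_band"][demo["age_band"][i]],
                    education=VOCABULARIES["education"][demo["education"][i]],
                    occupation=VOCABULARIES["occupation"][demo["occupation"][i]],
                    income_band=VOCABULARIES["income_band"][demo["income_band"][i]],
                    prenatal_visits_band=VOCABULARIES["prenatal_visits_band"][
                        demo["prenatal_visits_band"][i]
                    ],
                    family_size_band=VOCABULARIES["family_size_band"][
                        demo["family_size_band"][i]
                    ],
                    insured=VOCABULARIES["insured"][demo["insured"][i]] == "true",
                    state=HealthState(
                        *(int(levels[dim][i]) for dim in DIMENSIONS)
                    ),
                )
            )
    return out


def fixture_cohort() -> list[Respondent]:
    """The pinned 250-respondent reference cohort.

    Per group, the health-state multiset is fixed (:data:`_FIXTURE_STATES`)
    and each demographic attribute fills its published category counts,
    decorrelated across attributes by a fixed-seed permutation so that
    no attribute is a block function of another.  The result is fully
    deterministic: repeated calls return identical cohorts.
    """
    rng = np.random.default_rng(_FIXTURE_SHUFFLE_SEED)
    out: list[Respondent] = []
    for group in GROUPS:
        n = _GROUP_SIZES[group]
        prefix = "P" if group == "hiv_positive" else "N"

        states: list[str] = []
        for state_string, count in _FIXTURE_STATES[group]:
            states.extend([state_string] * count)
        assert len(states) == n

        assignments: dict[str, list[str]] = {}
        for fld in DEMOGRAPHIC_FIELDS:
            block = []
            for cat, count in _DEMOGRAPHIC_COUNTS[group][fld]:
                block.extend([cat] * count)
            assert len(block) == n
            order = rng.permutation(n)
            assignments[fld] = [block[j] for j in order]

        band_counters = {band: 0 for band in VOCABULARIES["age_band"]}
        for i in range(n):
            band = assignments["age_band"][i]
            lo, hi = AGE_RANGES[band]
            age = lo + band_counters[band] % (hi - lo + 1)
            band_counters[band] += 1
            out.append(
                Respondent(
                    id=f"{prefix}{i + 1:03d}",
                    group=group,
                    age_years=age,
                    age_band=band,
                    education=assignments["education"][i],
                    occupation=assignments["occupation"][i],
                    income_band=assignments["income_band"][i],
                    prenatal_visits_band=assignments["prenatal_visits_band"][i],
                    family_size_band=assignments["family_size_band"][i],
                    insured=assignments["insured"][i] == "true",
                    state=HealthState.from_string(states[i]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# CSV round-trip


def cohort_to_frame(respondents: Sequence[Respondent]):
    """Respondents as a pandas DataFrame in schema column order."""
    import pandas as pd

    rows = []
    for r in respondents:
        d = asdict(r)
        d["state"] = str(r.state)
        d["insured"] = "true" if r.insured else "false"
        rows.append(d)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_cohort_csv(respondents: Sequence[Respondent], path) -> None:
    """Write a cohort CSV (UTF-8, header row, LF newlines).

    Identical cohorts produce byte-identical files.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for r in respondents:
        writer.writerow(
            [
                r.id,
                r.group,
                r.age_years,
                r.age_band,
                r.education,
                r.occupation,
                r.income_band,
                r.prenatal_visits_band,
                r.family_size_band,
                "true" if r.insured else "false",
                str(r.state),
            ]
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path) -> list[Respondent]:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Raises :class:`CohortError` listing every invalid row (1-based data
    row numbers) if the file violates the schema.
    """
    respondents: list[Respondent] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise CohortError(f"cohort CSV missing columns: {sorted(missing)}")
        for row_number, row in enumerate(reader, start=1):
            try:
                respondents.append(
                    Respondent(
                        id=row["id"],
                        group=row["group"],
                        age_years=int(row["age_years"]),
                        age_band=row["age_band"],
                        education=row["education"],
                        occupation=row["occupation"],
                        income_band=row["income_band"],
                        prenatal_visits_band=row["prenatal_visits_band"],
                        family_size_band=row["family_size_band"],
                        insured=row["insured"].strip().lower() in ("true", "1", "yes"),
                        state=HealthState.from_string(row["state"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"row {row_number}: {exc}")
    if errors:
        raise CohortError("invalid cohort rows:\n" + "\n".join(errors))
    return respondents
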