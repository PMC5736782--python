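"""Domain types, packaged fixtures, CSV readers/writers and the full-analysis driver.

Three fixture tables ship with the package, transcribed from the source study's
printed compound tables:

* ``table1`` -- 18 P-glycoprotein substrates x 13 computed physico-chemical
  descriptors, labelled Group A (pulmonary absorption unaffected by Mdr1a/1b
  knockout) or Group B (absorption increased by knockout).
* ``table2`` -- experimental membrane affinity: LogK(IAM) from immobilised
  artificial membrane chromatography and multi-lamellar liposome vesicle (MLV)
  partitioning fractions.
* ``table3`` -- Ussing-chamber intestinal permeability coefficients (Papp,
  cm/s x 1e-6) in wild-type and Mdr1a/1b(-/-) tissue, with the knockout:wild-type
  ratio.
"""
from __future__ import annotations

import enum
import json
import math
import pathlib
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "CANONICAL_DESCRIPTORS",
    "INTEGER_DESCRIPTORS",
    "SchemaError",
    "AnalysisStageError",
    "Group",
    "CompoundRecord",
    "DescriptorMatrix",
    "fixture_path",
    "load_descriptor_table",
    "load_assay_table",
    "write_descriptor_table",
    "descriptor_dictionary",
    "run_full_analysis",
]

#: Canonical descriptor names, in fixture column order.
CANONICAL_DESCRIPTORS: tuple[str, ...] = (
    "cLogD7.4",
    "cLogP",
    "abraham_acidity",
    "abraham_basicity",
    "hbd",
    "hba",
    "hb_total",
    "rotatable_bonds",
    "abraham_volume",
    "abraham_polarizability",
    "psa",
    "mw",
    "abraham_mri",
)

#: Descriptors constrained to non-negative integers.
INTEGER_DESCRIPTORS = frozenset({"hbd", "hba", "hb_total", "rotatable_bonds"})

_FIXTURES = {
    "table1": "table1_descriptors.csv",
    "table2": "table2_membrane_affinity.csv",
    "table3": "table3_ussing_papp.csv",
}

_ASSAY_SCHEMAS = {
    "iam_mlv": ("name", "group", "logk_iam", "mlv_partitioning"),
    "ussing_papp": (
        "name",
        "group",
        "papp_wt_1e6",
        "papp_wt_sd_1e6",
        "papp_ko_1e6",
        "papp_ko_sd_1e6",
        "p_value",
        "ratio",
    ),
}


class SchemaError(ValueError):
    """A table does not match the expected column schema or value domain."""


class AnalysisStageError(RuntimeError):
    """An error raised while running a named stage of the full analysis."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"analysis stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


class Group(str, enum.Enum):
    A = "A"
    B = "B"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: a name, a class label and the 13 canonical descriptors."""

    name: str
    group: Group
    descriptors: Mapping[str, float]

    def __post_init__(self) -> None:
        names = set(self.descriptors)
        if names != set(CANONICAL_DESCRIPTORS):
            missing = sorted(set(CANONICAL_DESCRIPTORS) - names)
            extra = sorted(names - set(CANONICAL_DESCRIPTORS))
            raise SchemaError(
                f"compound {self.name!r}: descriptor set mismatch "
                f"(missing={missing}, unexpected={extra})"
            )
        for key, value in self.descriptors.items():
            if not math.isfinite(value):
                raise SchemaError(f"compound {self.name!r}: {key} is not finite")
            if key in INTEGER_DESCRIPTORS:
                if value < 0 or value != int(value):
                    raise SchemaError(
                        f"compound {self.name!r}: {key}={value} must be a "
                        "non-negative integer"
                    )

    @property
    def values(self) -> np.ndarray:
        return np.array(
            [self.descriptors[k] for k in CANONICAL_DESCRIPTORS], dtype=float
        )


@dataclass(frozen=True)
class DescriptorMatrix:
    """Ordered collection of :class:`CompoundRecord` (stable input order)."""

    records: tuple[CompoundRecord, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate compound names: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.records)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(r.group.value for r in self.records)

    @property
    def values(self) -> np.ndarray:
        """(n_compounds, 13) float array in canonical descriptor order."""
        return np.array([r.values for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(CANONICAL_DESCRIPTORS))
        df.insert(0, "group", list(self.groups))
        df.insert(0, "name", list(self.names))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorMatrix":
        records = []
        for _, row in df.iterrows():
            group = Group(str(row["group"])) if "group" in df.columns else Group.UNKNOWN
            records.append(
                CompoundRecord(
                    name=str(row["name"]),
                    group=group,
                    descriptors={k: float(row[k]) for k in CANONICAL_DESCRIPTORS},
                )
            )
        return cls(records=tuple(records))

    def subset(self, names: Iterable[str]) -> "DescriptorMatrix":
        wanted = list(names)
        by_name = {r.name: r for r in self.records}
        missing = [n for n in wanted if n not in by_name]
        if missing:
            raise KeyError(f"unknown compounds: {missing}")
        return DescriptorMatrix(records=tuple(by_name[n] for n in wanted))


def fixture_path(fixture_id: str) -> pathlib.Path:
    """Resolve a packaged fixture id (``table1``/``table2``/``table3``) to a path."""
    if fixture_id not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {fixture_id!r}; available: {sorted(_FIXTURES)}"
        )
    return pathlib.Path(
        str(resources.files("pgp_lungdisp.data").joinpath(_FIXTURES[fixture_id]))
    )


def _read_csv(source: str | pathlib.Path) -> pd.DataFrame:
    if isinstance(source, str) and source in _FIXTURES:
        source = fixture_path(source)
    try:
        df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{source}: empty file") from exc
    if df.empty:
        raise SchemaError(f"{source}: no data rows")
    return df


def _to_float(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        for i, raw in enumerate(df[col]):
            try:
                float(raw)
            except (TypeError, ValueError):
                name = df["name"].iloc[i] if "name" in df.columns else f"row {i}"
                raise SchemaError(
                    f"non-numeric value {raw!r} in column {col!r}, row {name!r}"
                ) from None
        out[col] = df[col].astype(float)
    return out


def load_descriptor_table(source: str | pathlib.Path) -> DescriptorMatrix:
    """Read a compound descriptor table (CSV or fixture id ``"table1"``).

    The file must carry ``name`` and ``group`` columns plus the 13 canonical
    descriptors.  The hydrogen-bond bookkeeping identity
    ``hb_total == hbd + hba`` is enforced on load.
    """
    df = _read_csv(source)
    required = ("name", "group") + CANONICAL_DESCRIPTORS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing columns {missing}")
    df = _to_float(df, CANONICAL_DESCRIPTORS)
    bad_groups = sorted(set(df["group"]) - {g.value for g in Group})
    if bad_groups:
        raise SchemaError(f"{source}: unknown group labels {bad_groups}")
    matrix = DescriptorMatrix.from_frame(df)
    for rec in matrix:
        d = rec.descriptors
        if d["hb_total"] != d["hbd"] + d["hba"]:
            raise SchemaError(
                f"compound {rec.name!r}: hb_total={d['hb_total']:g} does not "
                f"equal hbd+hba={d['hbd'] + d['hba']:g}"
            )
    return matrix


def load_assay_table(source: str | pathlib.Path, kind: str) -> pd.DataFrame:
    """Read an assay table of the given kind (``iam_mlv`` or ``ussing_papp``)."""
    if kind not in _ASSAY_SCHEMAS:
        raise ValueError(
            f"unknown assay kind {kind!r}; expected one of {sorted(_ASSAY_SCHEMAS)}"
        )
    df = _read_csv(source)
    schema = _ASSAY_SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: kind {kind!r} requires columns {missing}")
    numeric = [c for c in schema if c not in ("name", "group")]
    df = _to_float(df[list(schema)], numeric)
    names = list(df["name"])
    if len(names) != len(set(names)):
        raise SchemaError(f"{source}: duplicate compound names")
    return df.reset_index(drop=True)


def write_descriptor_table(matrix: DescriptorMatrix, path: str | pathlib.Path) -> None:
    """Write a descriptor matrix back to CSV (round-trips to full precision)."""
    df = matrix.to_frame()
    for col in INTEGER_DESCRIPTORS:
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False)


def descriptor_dictionary() -> pd.DataFrame:
    """The frozen data dictionary: canonical descriptor names, units, meaning."""
    path = resources.files("pgp_lungdisp.data").joinpath("descriptor_dictionary.csv")
    return pd.read_csv(str(path))


# ---------------------------------------------------------------------------
# Full-analysis driver
# ---------------------------------------------------------------------------


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def run_full_analysis(
    config: AnalysisConfig | None = None,
    out_dir: str | pathlib.Path | None = None,
) -> dict:
    """Run every fixture-based stage and return a machine-readable report.

    The report bundles the membrane-affinity group summaries and t-tests, the
    correlation analyses tying membrane affinity to the intestinal knockout
    effect, the Ussing-chamber ratio summaries, and the OPLS-DA classifier
    statistics.  With ``out_dir`` set, the report is written as ``report.json``
    together with intermediate CSV tables (fixture copies, recomputed ratios,
    scores and loadings).  Output is deterministic for a fixed configuration.
    """
    # imported here: these modules consume the types defined above
    from . import comparative_stats as cs
    from . import oplsda_qsar as oq
    from . import ussing_permeability as up

    config = config or AnalysisConfig()
    report: dict = {"config": config.to_dict()}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise AnalysisStageError(name, exc) from exc

        return deco

    @stage("load_fixtures")
    def _tables():
        return (
            load_descriptor_table("table1"),
            load_assay_table("table2", "iam_mlv"),
            load_assay_table("table3", "ussing_papp"),
        )

    table1, table2, table3 = _tables
    is_a = table2["group"] == "A"

    @stage("membrane_affinity")
    def membrane():
        out = {"group_means": {}, "t_tests": {}}
        for col in ("logk_iam", "mlv_partitioning"):
            for label, mask in (("A", is_a), ("B", ~is_a)):
                s = cs.summarize(table2.loc[mask, col].to_numpy(), label)
                out["group_means"].setdefault(label, {})[col] = {
                    "n": s.n,
                    "mean": _round(s.mean),
                    "sd": _round(s.sd),
                    "ci95": [_round(s.ci_low), _round(s.ci_high)],
                }
            t, p = cs.unpaired_t(
                table2.loc[is_a, col].to_numpy(), table2.loc[~is_a, col].to_numpy()
            )
            out["t_tests"][col] = {"t": _round(t), "p": _round(p)}
        return out

    report["membrane_affinity"] = membrane

    @stage("ussing")
    def ussing():
        recomputed = (table3["papp_ko_1e6"] / table3["papp_wt_1e6"]).to_numpy()
        per_compound = [
            {
                "name": row["name"],
                "group": row["group"],
                "papp_wt_1e6": row["papp_wt_1e6"],
                "papp_ko_1e6": row["papp_ko_1e6"],
                "ratio_printed": row["ratio"],
                "ratio_recomputed": _round(up.ko_wt_ratio(row["papp_ko_1e6"], row["papp_wt_1e6"])),
                "significant": bool(row["p_value"] < 0.05),
            }
            for _, row in table3.iterrows()
        ]
        ratios = dict(zip(table3["name"], table3["ratio"]))
        groups = dict(zip(table3["name"], table3["group"]))
        summaries = cs.group_fold_change(ratios, groups)
        summaries_excl = cs.group_fold_change(ratios, groups, exclude=("Saquinavir",))
        return {
            "per_compound": per_compound,
            "ratio_recompute_max_abs_dev": _round(
                float(np.max(np.abs(np.round(recomputed, 2) - table3["ratio"].to_numpy())))
            ),
            "group_ratio_summary": {
                "A": _summary_dict(summaries["A"]),
                "B": _summary_dict(summaries["B"]),
                "A_excluding_saquinavir": _summary_dict(summaries_excl["A"]),
            },
            "nonsignificant_compounds": [
                r["name"] for r in per_compound if not r["significant"]
            ],
        }

    report["ussing"] = ussing

    @stage("correlations")
    def correlations():
        merged = table2.merge(table3[["name", "papp_wt_1e6", "ratio"]], on="name")
        pear = cs.pearson(merged["logk_iam"].to_numpy(), merged["mlv_partitioning"].to_numpy())
        sp1 = cs.spearman(merged["logk_iam"].to_numpy(), merged["ratio"].to_numpy())
        sp2 = cs.spearman(merged["papp_wt_1e6"].to_numpy(), merged["ratio"].to_numpy())
        return {
            "pearson_logkiam_mlv": _corr_dict(pear),
            "spearman_logkiam_intestinal_ratio": _corr_dict(sp1),
            "spearman_wt_papp_intestinal_ratio": _corr_dict(sp2),
        }

    report["correlations"] = correlations

    @stage("oplsda")
    def oplsda():
        s = config.oplsda
        model = oq.fit_oplsda(
            table1,
            n_orth=s.n_orthogonal,
            folds=s.folds,
            y_coding=dict(s.y_coding),
            threshold=s.threshold,
            cv_scheme=s.cv_scheme,
        )
        scores, loadings = oq.export_scores_loadings(model)
        polarity = (
            "abraham_acidity",
            "abraham_basicity",
            "psa",
            "hbd",
            "hba",
            "hb_total",
        )
        w = dict(zip(loadings["descriptor"], loadings["predictive_loading"]))
        b_side = float(
            np.mean([t for t, g in zip(model.t_pred, table1.groups) if g == "B"])
        )
        polarity_on_a_side = all(np.sign(w[d]) != np.sign(b_side) for d in polarity)
        return {
            "r2y": _round(model.r2y),
            "q2": _round(model.q2),
            "n_orth": model.n_orth,
            "folds": s.folds,
            "cv_scheme": s.cv_scheme,
            "misclassified": list(model.misclassified_names),
            "polarity_descriptors_on_group_a_side": bool(polarity_on_a_side),
            "_scores": scores,
            "_loadings": loadings,
        }

    opls_out = oplsda
    scores_df = opls_out.pop("_scores")
    loadings_df = opls_out.pop("_loadings")
    report["oplsda"] = opls_out

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table1.to_frame().to_csv(out / "table1_descriptors.csv", index=False)
        table2.to_csv(out / "table2_membrane_affinity.csv", index=False)
        table3.to_csv(out / "table3_ussing_papp.csv", index=False)
        pd.DataFrame(report["ussing"]["per_compound"]).to_csv(
            out / "ussing_ratios.csv", index=False
        )
        scores_df.to_csv(out / "oplsda_scores.csv", index=False)
        loadings_df.to_csv(out / "oplsda_loadings.csv", index=False)
        (out / "report.json").write_bytes(
            json.dumps(report, indent=2, sort_keys=True).encode()
        )
    return report


def _summary_dict(s) -> dict:
    return {
        "n": s.n,
        "mean": _round(s.mean),
        "sd": _round(s.sd),
        "ci95": [_round(s.ci_low), _round(s.ci_high)],
    }


def _corr_dict(c) -> dict:
    return {
        "coefficient": _round(c.coefficient),
        "p": _round(c.p_value, 8),
        "n": c.n,
        "method": c.method,
    }
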