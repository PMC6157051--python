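"""Readers and writers for the tabular interchange formats.

Two input dialects are supported for call sets:

* wide ("matrix"): a prediction-by-submission CSV with coordinate columns
  ``CHROM``/``END`` (or ``chrom``/``pos``) followed by one 0/1 column per
  submission;
* long: a TSV with columns ``caller``, ``chrom``, ``pos`` — one row per
  (caller, variant) call. The long form is the canonical internal shape.

Truth tables are CSVs with columns ``chrom``, ``pos``, ``truth`` (1 = true
positive, 0 = not). Selections and metrics are written as TSV with a stable
column order; undefined scores are serialized as the literal token ``NA``.

Chromosome labels are compared as opaque strings ("chr1" != "1"); pass
``normalize_chrom=True`` to strip a leading "chr" on read.
"""

from __future__ import annotations

import math
from os import PathLike
from typing import Sequence

import pandas as pd

from .evaluation import MetricsRecord
from .model import CallProfile, Selection, TruthTable, VariantKey

_COORD_ALIASES = {"CHROM": "chrom", "END": "pos", "chrom": "chrom", "pos": "pos"}


def _norm_chrom(label: str, normalize: bool) -> str:
    label = str(label)
    if normalize and label.lower().startswith("chr"):
        return label[3:]
    return label


# -- call sets -----------------------------------------------------------


def read_prediction_matrix(
    path: str | PathLike, normalize_chrom: bool = False
) -> CallProfile:
    """Read a wide prediction-by-submission matrix CSV.

    Columns: CHROM, END (or chrom, pos), then one 0/1 column per submission.
    Submission order in the file is preserved as the caller order.
    """
    df = pd.read_csv(path, dtype={0: str})
    coord_cols = [c for c in df.columns if c in _COORD_ALIASES]
    if len({_COORD_ALIASES[c] for c in coord_cols}) != 2:
        raise ValueError(
            f"{path}: need coordinate columns CHROM/END (or chrom/pos), got {list(df.columns)}"
        )
    chrom_col = next(c for c in coord_cols if _COORD_ALIASES[c] == "chrom")
    pos_col = next(c for c in coord_cols if _COORD_ALIASES[c] == "pos")
    submissions = [c for c in df.columns if c not in (chrom_col, pos_col)]
    if not submissions:
        raise ValueError(f"{path}: no submission columns")

    flags = df[submissions]
    if not flags.isin([0, 1]).all().all():
        bad = flags[~flags.isin([0, 1]).all(axis=1)].index[0]
        raise ValueError(f"{path}: non-binary membership value at row {bad}")

    keys = [
        VariantKey(_norm_chrom(c, normalize_chrom), int(p))
        for c, p in zip(df[chrom_col], df[pos_col])
    ]
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate (CHROM, END) rows")

    membership: dict[VariantKey, set[str]] = {}
    values = flags.to_numpy()
    for i, key in enumerate(keys):
        group = {s for s, flag in zip(submissions, values[i]) if flag}
        if not group:
            raise ValueError(f"{path}: variant with no caller at {key.chrom}:{key.pos}")
        membership[key] = group
    return CallProfile(submissions, membership)


def write_prediction_matrix(profile: CallProfile, path: str | PathLike) -> None:
    """Write a profile as a wide CSV (columns CHROM, END, one per caller)."""
    rows = []
    for v in profile.variants:
        group = profile.membership[v]
        rows.append(
            [v.chrom, v.pos] + [int(c in group) for c in profile.callers]
        )
    df = pd.DataFrame(rows, columns=["CHROM", "END", *profile.callers])
    df.to_csv(path, index=False)


def read_long_calls(
    path: str | PathLike, normalize_chrom: bool = False
) -> CallProfile:
    """Read a long call table TSV with columns caller, chrom, pos.

    Caller order is first-appearance order; duplicate (caller, variant)
    rows collapse to one call.
    """
    df = pd.read_csv(path, sep="\t", dtype={"caller": str, "chrom": str})
    missing = {"caller", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no calls")
    callers = list(dict.fromkeys(df["caller"]))
    membership: dict[VariantKey, set[str]] = {}
    for caller, chrom, pos in zip(df["caller"], df["chrom"], df["pos"]):
        key = VariantKey(_norm_chrom(chrom, normalize_chrom), int(pos))
        membership.setdefault(key, set()).add(caller)
    return CallProfile(callers, membership)


def write_long_calls(profile: CallProfile, path: str | PathLike) -> None:
    rows = [
        (c, v.chrom, v.pos)
        for c in profile.callers
        for v in profile.calls_of(c)
    ]
    pd.DataFrame(rows, columns=["caller", "chrom", "pos"]).to_csv(
        path, sep="\t", index=False
    )


def read_calls(
    path: str | PathLike, dialect: str = "matrix", normalize_chrom: bool = False
) -> CallProfile:
    """Read a call set in either dialect ("matrix" or "long")."""
    if dialect == "matrix":
        return read_prediction_matrix(path, normalize_chrom)
    if dialect == "long":
        return read_long_calls(path, normalize_chrom)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'matrix' or 'long'")


# -- truth tables --------------------------------------------------------


def read_truth_table(
    path: str | PathLike, normalize_chrom: bool = False
) -> TruthTable:
    """Read a truth CSV with columns chrom, pos, truth (1/0)."""
    df = pd.read_csv(path, dtype={"chrom": str})
    missing = {"chrom", "pos", "truth"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not df["truth"].isin([0, 1]).all():
        bad = df.loc[~df["truth"].isin([0, 1]), "truth"].iloc[0]
        raise ValueError(f"{path}: truth value outside {{0,1}}: {bad!r}")
    labels: dict[VariantKey, bool] = {}
    for chrom, pos, truth in zip(df["chrom"], df["pos"], df["truth"]):
        key = VariantKey(_norm_chrom(chrom, normalize_chrom), int(pos))
        value = bool(truth)
        if key in labels and labels[key] != value:
            raise ValueError(
                f"{path}: conflicting truth labels for {key.chrom}:{key.pos}"
            )
        labels[key] = value
    return TruthTable(labels)


def write_truth_table(truth: TruthTable, path: str | PathLike) -> None:
    rows = [(v.chrom, v.pos, int(t)) for v, t in sorted(truth.labels.items())]
    pd.DataFrame(rows, columns=["chrom", "pos", "truth"]).to_csv(path, index=False)


# -- selections ----------------------------------------------------------

_SELECTION_COLUMNS = ["chrom", "pos", "attribution", "strategy", "seed"]


def write_selection(selection: Selection, path: str | PathLike) -> None:
    """Write a selection as TSV (chrom, pos, attribution, strategy, seed)."""
    rows = [
        (v.chrom, v.pos, selection.attribution[v], selection.strategy_name, selection.seed)
        for v in selection.variants
    ]
    pd.DataFrame(rows, columns=_SELECTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_selection(path: str | PathLike) -> Selection:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "attribution": str})
    missing = set(_SELECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    variants = tuple(VariantKey(c, int(p)) for c, p in zip(df["chrom"], df["pos"]))
    attribution = {v: a for v, a in zip(variants, df["attribution"])}
    if df.empty:
        return Selection(variants=(), attribution={}, strategy_name="", seed=0)
    return Selection(
        variants=variants,
        attribution=attribution,
        strategy_name=str(df["strategy"].iloc[0]),
        seed=int(df["seed"].iloc[0]),
    )


# -- metrics -------------------------------------------------------------

_METRICS_COLUMNS = ["caller", "mode", "TP", "FP", "FN", "precision", "recall", "F1"]


def _fmt_score(x: float | None) -> str:
    return "NA" if x is None else repr(float(x))


def write_metrics(records: Sequence[MetricsRecord], path: str | PathLike) -> None:
    """Write metric records as TSV; undefined scores become the token NA."""
    rows = [
        (
            r.caller,
            r.mode,
            r.tp,
            r.fp,
            r.fn,
            _fmt_score(r.precision),
            _fmt_score(r.recall),
            _fmt_score(r.f1),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_METRICS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metrics(path: str | PathLike) -> list[MetricsRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"caller": str, "mode": str}, keep_default_na=False
    )
    missing = set(_METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def parse(x: str) -> float | None:
        if x == "NA":
            return None
        v = float(x)
        if math.isnan(v):
            return None
        return v

    return [
        MetricsRecord(
            caller=row["caller"],
            mode=row["mode"],
            tp=int(row["TP"]),
            fp=int(row["FP"]),
            fn=int(row["FN"]),
            precision=parse(str(row["precision"])),
            recall=parse(str(row["recall"])),
            f1=parse(str(row["F1"])),
        )
        for _, row in df.iterrows()
    ]
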