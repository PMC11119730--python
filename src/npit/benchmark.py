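"""Seeded sweep engine over the benchmark cases.

For every requested (case x quantity x estimator x hyperparameter x sample
size x seed) cell the engine draws a sample (the same sample is shared by
every estimator within a cell, so methods are compared on identical data),
runs the estimator and records the value in nats.  Records aggregate into
an evaluation table of mean, 2.5/97.5 percentile band and signed relative
error of the mean against the true value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import binning, distributions, kde, knn
from .distributions import BenchmarkCase, builtin_cases, get_case

__all__ = [
    "EstimatorSpec",
    "SweepConfig",
    "EstimateRecord",
    "run_sweep",
    "summarize",
    "records_to_frame",
    "write_records",
    "read_records",
    "DEFAULT_SIZES",
]

logger = logging.getLogger("npit.benchmark")

#: default sample-size ladder
DEFAULT_SIZES = (100, 500, 1000, 5000, 10000, 50000, 100000)

#: largest k-NN sample in 10 dimensions
KNN_10D_CEILING = 50_000

_RECORD_COLUMNS = [
    "case",
    "quantity",
    "estimator",
    "variant",
    "n",
    "seed",
    "value",
    "raw_value",
    "excluded",
]


@dataclass(frozen=True)
class EstimatorSpec:
    """One estimator with fixed hyperparameters."""

    method: str  # "kde" | "binning" | "qs" | "knn"
    params: tuple = ()

    @classmethod
    def kde(cls, mode: str = "resubstitution") -> "EstimatorSpec":
        return cls("kde", (("mode", mode),))

    @classmethod
    def binning(cls, rule: str = "scott") -> "EstimatorSpec":
        return cls("binning", (("rule", rule),))

    @classmethod
    def qs(cls, alpha: float = 0.25, nk: int = 500) -> "EstimatorSpec":
        return cls("qs", (("alpha", alpha), ("nk", nk)))

    @classmethod
    def knn(cls, k: int = 1) -> "EstimatorSpec":
        return cls("knn", (("k", k),))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    @property
    def variant(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.method}[{inner}]"

    def supports(self, quantity: str, dim: int) -> bool:
        if self.method == "qs":
            return quantity == "entropy" and dim == 1
        return True

    def size_ceiling(self, quantity: str, dim: int) -> int | None:
        if self.method == "kde":
            mode = self.param_dict["mode"]
            return kde.MAX_N_INTEGRAL if mode == "integral" else kde.MAX_N_RESUBSTITUTION
        if self.method == "knn" and dim >= 10:
            return KNN_10D_CEILING
        return None


@dataclass(frozen=True)
class EstimateRecord:
    """One estimate: a cell of the sweep at one seed."""

    case: int
    quantity: str
    estimator: str
    variant: str
    n: int
    seed: int
    value: float
    raw_value: float | None = None  # pre-clipping value where applicable
    excluded: int | None = None  # excluded p-points (binning KL)


@dataclass(frozen=True)
class SweepConfig:
    """What to sweep: case, quantities, estimators, sizes and seeds."""

    case_id: int
    quantities: tuple[str, ...]
    estimators: tuple[EstimatorSpec, ...]
    sizes: tuple[int, ...] = DEFAULT_SIZES
    n_seeds: int = 300
    base_seed: int = 0
    kl_empty_bin: str = "exclude"

    def validate(self, case: BenchmarkCase) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        for q in self.quantities:
            if q not in case.quantities:
                raise ValueError(
                    f"case {case.case_id} ({case.name}) does not define {q!r}; "
                    f"available quantities: {case.quantities}"
                )


def _cell_seed(base: int, case_id: int, size_index: int, rep: int, stream: int):
    """Reproducible per-cell RNG seed; `stream` separates p/q/bootstrap draws."""
    return np.random.SeedSequence(entropy=base, spawn_key=(case_id, size_index, rep, stream))


def _estimate(
    spec: EstimatorSpec,
    quantity: str,
    case: BenchmarkCase,
    sample_p: np.ndarray,
    sample_q: np.ndarray | None,
    qs_seed,
    kl_empty_bin: str,
) -> tuple[float, float | None, int | None]:
    params = spec.param_dict
    if spec.method == "kde":
        mode = params["mode"]
        if quantity == "entropy":
            return kde.kde_entropy(sample_p, mode=mode), None, None
        if quantity == "kl":
            return kde.kde_kl(sample_p, sample_q, mode=mode), None, None
        return kde.kde_mi(sample_p, case.mi_split, mode=mode), None, None
    if spec.method == "binning":
        rule = params["rule"]
        if quantity == "entropy":
            return binning.bin_entropy(sample_p, rule=rule), None, None
        if quantity == "kl":
            value, excluded = binning.bin_kl(
                sample_p, sample_q, rule=rule, empty_bin=kl_empty_bin, return_excluded=True
            )
            return value, None, excluded
        return binning.bin_mi(sample_p, case.mi_split, rule=rule), None, None
    if spec.method == "qs":
        if quantity != "entropy":
            raise ValueError("Quantile Spacing estimates entropy only")
        return (
            binning.qs_entropy(sample_p, alpha=params["alpha"], nk=params["nk"], seed=qs_seed),
            None,
            None,
        )
    if spec.method == "knn":
        k = params["k"]
        if quantity == "entropy":
            return knn.kl_entropy(sample_p, k=k), None, None
        if quantity == "kl":
            return knn.knn_kl(sample_p, sample_q, k=k), None, None
        clipped, raw = knn.kraskov_mi(sample_p, case.mi_split, k=k, return_raw=True)
        return clipped, raw, None
    raise ValueError(f"unknown estimator method {spec.method!r}")


def run_sweep(config: SweepConfig, failures: list | None = None) -> list[EstimateRecord]:
    """Run the sweep; returns one record per successful cell x seed.

    Estimator failures are logged (and appended to `failures` as
    (cell-description, reason) pairs when a list is supplied); the sweep
    continues.  Cells beyond an estimator's documented size ceiling are
    clipped silently.
    """
    case = get_case(config.case_id)
    config.validate(case)
    records: list[EstimateRecord] = []
    needs_q = "kl" in config.quantities
    for size_index, n in enumerate(config.sizes):
        for rep in range(config.n_seeds):
            sample_p = distributions.sample(
                case.p, n, _cell_seed(config.base_seed, case.case_id, size_index, rep, 0)
            )
            sample_q = (
                distributions.sample(
                    case.q, n, _cell_seed(config.base_seed, case.case_id, size_index, rep, 1)
                )
                if needs_q
                else None
            )
            qs_seed = _cell_seed(config.base_seed, case.case_id, size_index, rep, 2)
            for quantity in config.quantities:
                for spec in config.estimators:
                    if not spec.supports(quantity, case.dim):
                        continue
                    ceiling = spec.size_ceiling(quantity, case.dim)
                    if ceiling is not None and n > ceiling:
                        continue
                    try:
                        value, raw, excluded = _estimate(
                            spec, quantity, case, sample_p, sample_q, qs_seed,
                            config.kl_empty_bin,
                        )
                    except Exception as exc:  # noqa: BLE001 - per-cell isolation
                        desc = f"case={case.case_id} {quantity} {spec.variant} n={n} seed={rep}"
                        logger.warning("cell failed: %s: %s", desc, exc)
                        if failures is not None:
                            failures.append((desc, str(exc)))
                        continue
                    records.append(
                        EstimateRecord(
                            case=case.case_id,
                            quantity=quantity,
                            estimator=spec.method,
                            variant=spec.variant,
                            n=n,
                            seed=rep,
                            value=value,
                            raw_value=raw,
                            excluded=excluded,
                        )
                    )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Records as a DataFrame with the documented fixed column order."""
    if isinstance(records, pd.DataFrame):
        return records[_RECORD_COLUMNS].copy()
    frame = pd.DataFrame(
        [
            {
                "case": r.case,
                "quantity": r.quantity,
                "estimator": r.estimator,
                "variant": r.variant,
                "n": r.n,
                "seed": r.seed,
                "value": r.value,
                "raw_value": np.nan if r.raw_value is None else r.raw_value,
                "excluded": np.nan if r.excluded is None else r.excluded,
            }
            for r in records
        ],
        columns=_RECORD_COLUMNS,
    )
    return frame


def write_records(path, records) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"record file {path} is missing columns {sorted(missing)}")
    return frame[_RECORD_COLUMNS]


def _default_references(frame: pd.DataFrame) -> dict[tuple[int, str], float]:
    refs = {}
    for case_id, quantity in frame.groupby(["case", "quantity"]).groups:
        case = get_case(int(case_id))
        refs[(int(case_id), quantity)] = case.reference(quantity).value
    return refs


def summarize(records, references: dict | None = None) -> pd.DataFrame:
    """Aggregate records into the evaluation table.

    One row per (case, quantity, estimator, variant, n): mean estimate,
    2.5/97.5 percentiles over seeds, the reference value, and the signed
    relative error of the mean, (mean - ref)/|ref|.  Cells whose reference
    is zero report the absolute error instead and are flagged in
    ``error_kind``.
    """
    frame = records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to summarize")
    if references is None:
        references = _default_references(frame)
    rows = []
    keys = ["case", "quantity", "estimator", "variant", "n"]
    for key, group in frame.groupby(keys, sort=True):
        case_id, quantity = int(key[0]), key[1]
        try:
            ref = references[(case_id, quantity)]
        except KeyError as exc:
            raise KeyError(
                f"no reference value supplied for case {case_id} quantity {quantity!r}"
            ) from exc
        values = group["value"].to_numpy(dtype=float)
        mean = float(values.mean())
        if ref == 0.0:
            err, kind = mean - ref, "absolute"
        else:
            err, kind = (mean - ref) / abs(ref), "relative"
        rows.append(
            {
                "case": case_id,
                "quantity": quantity,
                "estimator": key[2],
                "variant": key[3],
                "n": int(key[4]),
                "n_seeds": int(len(values)),
                "mean": mean,
                "p2.5": float(np.percentile(values, 2.5)),
                "p97.5": float(np.percentile(values, 97.5)),
                "reference": float(ref),
                "error": float(err),
                "error_kind": kind,
            }
        )
    return pd.DataFrame(rows)
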