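"""Reference molecular assays: the NGS arm-level FC rule and the FISH call.

These are the label-generating rules the imaging model is trained against
and compared with:

* **NGS rule** — per-gene log2 fold changes on the 1p and 19q arms are
  averaged per arm (on the linear scale by default, see below) and a tumor
  is called oligodendroglioma when *both* arm means fall strictly below
  0.8; otherwise astrocytoma. Means exactly at the threshold are routed to
  astrocytoma and flagged borderline, mirroring the manual copy-number
  plot review such genomes get in practice.
* **FISH rule** — among nuclei bearing two centromeric control signals,
  an arm is deleted when strictly more than 50% show a single
  target-region signal; more than 60 such nuclei must be evaluated for
  the call to be valid. Codeletion requires both arms deleted.

Scale note: the 0.8 threshold and the 0.5-0.8 hemizygous-loss range are
linear-scale fold changes (1.0 = diploid), so per-gene log2 values are
converted with ``2**log2_fc`` before averaging; ``scale="log2"`` instead
averages in log2 space and exponentiates the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .synthetic import TumorType

GENE_FC_COLUMNS = ("gene", "arm", "log2_fc")


class InsufficientNucleiError(ValueError):
    """Raised when too few control-signal nuclei were evaluated for FISH."""


@dataclass(frozen=True)
class FISHCount:
    """Nucleus tally for one arm's FISH assay.

    ``n_evaluated`` counts nuclei possessing two centromeric (control)
    signals; ``n_single_target`` counts those among them with only one
    target-region signal.
    """

    arm: str
    n_evaluated: int
    n_single_target: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_single_target <= self.n_evaluated):
            raise ValueError("need 0 <= n_single_target <= n_evaluated")


class NGSCall(NamedTuple):
    tumor_type: TumorType
    borderline: bool


def load_gene_fc_table(path) -> pd.DataFrame:
    """Read a per-gene FC table CSV with columns gene, arm, log2_fc."""
    df = pd.read_csv(path)
    missing = set(GENE_FC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene FC table is missing columns {sorted(missing)}")
    return df


def mean_arm_fc(table: pd.DataFrame, arm: str, scale: str = "linear") -> float:
    """Mean linear-scale fold change of one chromosome arm.

    ``scale="linear"`` (default) averages ``2**log2_fc`` per gene;
    ``scale="log2"`` averages in log2 space and returns ``2**mean``.
    """
    sub = table.loc[table["arm"] == arm, "log2_fc"].to_numpy(dtype=np.float64)
    if sub.size == 0:
        raise ValueError(f"no genes on arm {arm!r}")
    if not np.all(np.isfinite(sub)):
        raise ValueError(f"non-finite log2 FC values on arm {arm!r}")
    if scale == "linear":
        return float(np.mean(2.0**sub))
    if scale == "log2":
        return float(2.0 ** np.mean(sub))
    raise ValueError(f"unknown scale {scale!r}; expected 'linear' or 'log2'")


def ngs_classify(mean_1p: float, mean_19q: float, threshold: float = 0.8) -> NGSCall:
    """Arm-mean FC rule: oligodendroglioma iff both means are strictly
    below the threshold; exact ties go to astrocytoma with a borderline
    flag."""
    if not (np.isfinite(mean_1p) and np.isfinite(mean_19q)):
        raise ValueError("arm means must be finite")
    if mean_1p < threshold and mean_19q < threshold:
        return NGSCall(TumorType.OLIGODENDROGLIOMA, borderline=False)
    borderline = mean_1p == threshold or mean_19q == threshold
    return NGSCall(TumorType.ASTROCYTOMA, borderline=borderline)


def fish_deletion_call(
    count: FISHCount,
    min_nuclei: int = 60,
    ratio_threshold: float = 0.5,
) -> str:
    """Single-arm FISH call: deleted iff the single-target signal ratio is
    strictly above ``ratio_threshold``.

    Strictly more than ``min_nuclei`` evaluable nuclei are required.
    """
    if count.n_evaluated <= min_nuclei:
        raise InsufficientNucleiError(
            f"only {count.n_evaluated} nuclei with two control signals "
            f"evaluated; more than {min_nuclei} required"
        )
    ratio = count.n_single_target / count.n_evaluated
    return "deleted" if ratio > ratio_threshold else "not_deleted"


def fish_codeletion(call_1p: str, call_19q: str) -> str:
    """Joint 1p/19q status: codeleted iff both arms are deleted."""
    for call in (call_1p, call_19q):
        if call not in ("deleted", "not_deleted"):
            raise ValueError(f"unknown FISH call {call!r}")
    return "codeleted" if call_1p == "deleted" and call_19q == "deleted" else "not_codeleted"
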