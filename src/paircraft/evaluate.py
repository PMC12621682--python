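"""Design-screening metrics and synthetic chemical-probing emulation.

Covers the quantitative layer used to screen nucleic-acid designs:

* base-pair F1 between a predicted and a designed secondary structure;
* simulated SHAPE-style reactivity profiles (paired nucleotides are
  protected and read low, unpaired nucleotides read high) and a
  concordance score quantifying how well a profile matches a target
  structure.  The concordance is a balanced accuracy at a reactivity
  threshold — a deliberately simple, documented surrogate for proprietary
  aggregate probing scores, and named differently to avoid conflation;
* threshold filtering of design records by predictor confidence and
  self-consistency RMSDs;
* sequence preparation helpers (5' transcription leader).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .secstruct import SecondaryStructure

# -- secondary-structure F1 --------------------------------------------------


def ss_f1(
    predicted: Iterable[tuple[int, int]],
    designed: Iterable[tuple[int, int]],
) -> tuple[float, float, float]:
    """Precision, recall and F1 over exact (i, j) base-pair identity.

    Two empty sets agree perfectly on "no pairs" and score (1, 1, 1).
    """
    p = {(min(i, j), max(i, j)) for i, j in predicted}
    d = {(min(i, j), max(i, j)) for i, j in designed}
    if not p and not d:
        return (1.0, 1.0, 1.0)
    inter = len(p & d)
    precision = inter / len(p) if p else 0.0
    recall = inter / len(d) if d else 0.0
    f1 = 2.0 * inter / (len(p) + len(d))
    return (precision, recall, f1)


# -- reactivity profiles -----------------------------------------------------


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-nucleotide chemical reactivity (non-negative, one per position)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float).ravel()
        object.__setattr__(self, "values", v)
        if v.size == 0:
            raise ValidationError("empty reactivity profile")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValidationError("reactivities must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def to_file(self, path) -> None:
        """Two-column tab-separated text: 0-based position, reactivity."""
        with open(path, "w") as fh:
            fh.write("# position\treactivity\n")
            for i, v in enumerate(self.values):
                fh.write(f"{i}\t{v:.6f}\n")

    @classmethod
    def from_file(cls, path) -> "ReactivityProfile":
        pos, val = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split()[:2]
                pos.append(int(a))
                val.append(float(b))
        order = np.argsort(pos)
        return cls(values=np.asarray(val, float)[order])


def simulate_reactivity(
    ss: SecondaryStructure,
    mu_paired: float = 0.2,
    mu_unpaired: float = 1.0,
    sigma: float = 0.3,
    seed: int = 0,
) -> ReactivityProfile:
    """Generate a synthetic SHAPE-style reactivity profile for a structure.

    Paired positions are protected from chemical modification and centre at
    ``mu_paired``; unpaired (loop) positions are flexible and centre at
    ``mu_unpaired``.  Noise is multiplicative log-normal (reactivities are
    non-negative and right-skewed): each position draws
    ``mu * exp(sigma * z - sigma^2 / 2)`` with standard-normal ``z``, so the
    expected value of each draw is exactly its ``mu``; ``sigma = 0`` gives
    the class means verbatim.
    """
    if not (mu_unpaired > mu_paired >= 0):
        raise ValidationError(
            f"need mu_unpaired > mu_paired >= 0, got {mu_unpaired}, {mu_paired}"
        )
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    paired = ss.paired_indices()
    mu = np.array([mu_paired if i in paired else mu_unpaired for i in range(ss.length)])
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(ss.length)
    vals = mu * np.exp(sigma * z - sigma**2 / 2.0)
    return ReactivityProfile(values=np.maximum(vals, 0.0))


def reactivity_concordance(
    profile: ReactivityProfile,
    ss: SecondaryStructure,
    threshold: float = 0.5,
) -> float:
    """Balanced accuracy of reactivity-based paired/unpaired classification.

    A position is called unpaired when its reactivity exceeds ``threshold``.
    The score is the mean of the per-class fractions correct (paired called
    paired, unpaired called unpaired), so it is insensitive to the
    paired/unpaired imbalance of the structure; with only one class present
    the single defined fraction is returned.  1.0 means the profile is fully
    consistent with the structure; 0.5 is chance; 0.0 fully inverted.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    if len(profile) != ss.length:
        raise ValidationError(
            f"profile length {len(profile)} != structure length {ss.length}"
        )
    paired = np.zeros(ss.length, bool)
    paired[list(ss.paired_indices())] = True
    called_unpaired = profile.values > threshold
    fracs = []
    if paired.any():
        fracs.append(float((~called_unpaired[paired]).mean()))
    if (~paired).any():
        fracs.append(float(called_unpaired[~paired].mean()))
    return float(np.mean(fracs))


# -- design-record filtering -------------------------------------------------


@dataclass
class DesignRecord:
    """Per-design screening metrics as produced by structure predictors."""

    design_id: str
    plddt: float | None = None
    backbone_rmsd: float | None = None
    allatom_rmsd: float | None = None
    f1: float | None = None
    tm_score: float | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.plddt is not None and not (0.0 <= self.plddt <= 1.0):
            # predictors report pLDDT on 0-1 or 0-100; normalize the latter
            if 1.0 < self.plddt <= 100.0:
                self.plddt = self.plddt / 100.0
            else:
                raise ValidationError(
                    f"{self.design_id}: pLDDT {self.plddt} outside [0, 1] (or [0, 100])"
                )
        for name in ("backbone_rmsd", "allatom_rmsd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.design_id}: {name} must be >= 0, got {v}")


#: Self-consistency defaults: keep designs with predictor confidence
#: strictly above 0.87 and self-consistency RMSDs strictly below 2.2 A
#: (backbone) and 3.5 A (all-atom).
DEFAULT_THRESHOLDS: dict[str, tuple[str, float]] = {
    "plddt": (">", 0.87),
    "backbone_rmsd": ("<", 2.2),
    "allatom_rmsd": ("<", 3.5),
}

_FILTERABLE = ("plddt", "backbone_rmsd", "allatom_rmsd", "f1", "tm_score", "coverage")


def filter_designs(
    records: Sequence[DesignRecord],
    thresholds: Mapping[str, tuple[str, float]] | None = None,
) -> list[DesignRecord]:
    """Keep records satisfying every bound, preserving input order.

    ``thresholds`` maps field names to ``(direction, value)`` with strict
    ``">"`` (confidence-like) or ``"<"`` (error-like) comparison; the
    default is the standard self-consistency screen
    (pLDDT > 0.87, backbone RMSD < 2.2, all-atom RMSD < 3.5).  A record
    missing a field fails only the bounds that reference that field.
    """
    bounds = DEFAULT_THRESHOLDS if thresholds is None else dict(thresholds)
    for name, (op, _) in bounds.items():
        if name not in _FILTERABLE:
            raise ValidationError(f"unknown filter field {name!r}")
        if op not in ("<", ">"):
            raise ValidationError(f"filter direction must be '<' or '>', got {op!r}")
    out = []
    for rec in records:
        ok = True
        for name, (op, bound) in bounds.items():
            v = getattr(rec, name)
            if v is None:
                ok = False
                break
            if op == ">" and not v > bound:
                ok = False
                break
            if op == "<" and not v < bound:
                ok = False
                break
        if ok:
            out.append(rec)
    return out


def records_from_table(path_or_df) -> list[DesignRecord]:
    """Load design records from a delimited table with a header row.

    Recognized columns: design_id (or id/name), plddt, backbone_rmsd,
    allatom_rmsd, f1, tm_score, coverage.  Extra columns are ignored.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep=None, engine="python")
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    id_col = next((c for c in ("design_id", "id", "name") if c in df.columns), None)
    if id_col is None:
        raise ValidationError("design table needs a design_id / id / name column")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in _FILTERABLE:
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = float(row[f])
        out.append(DesignRecord(design_id=str(row[id_col]), **kwargs))
    return out


def records_to_table(records: Sequence[DesignRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"design_id": r.design_id, **{f: getattr(r, f) for f in _FILTERABLE}}
            for r in records
        ]
    )


# -- sequence preparation ----------------------------------------------------

_NT_ALPHABET = set("ACGUT")


def prepend_leader(sequence: str, leader: str = "GG") -> str:
    """Prepend a 5' transcription leader (default the two-nucleotide GG
    leader used to promote T7 transcription).

    The leader is added unconditionally — a sequence already starting with
    GG still gains the full leader length.
    """
    for name, s in (("sequence", sequence), ("leader", leader)):
        bad = set(s.upper()) - _NT_ALPHABET
        if bad:
            raise ValidationError(f"{name} contains non-nucleotide characters {sorted(bad)}")
    return leader + sequence
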