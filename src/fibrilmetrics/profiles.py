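"""Per-residue sequence profiles of the fibril protein.

Covers Kyte-Doolittle hydropathy, threshold/run scans of per-residue
scales (packing-density and AGGRESCAN-style amyloidogenicity), ingestion
of external aggregation-predictor output, the 0-5 consensus amyloid score,
and germline-vs-patient mutation listing and structural classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError, ParseError
from .scales import (AGGRESCAN_A3V, AGGRESCAN_THRESHOLD, KYTE_DOOLITTLE,
                     PACKING_DENSITY, PACKING_DENSITY_THRESHOLD,
                     RESIDUE_CHARGE)
from .structure import AtomicModel

PREDICTOR_NAMES = ("WALTZ", "TANGO", "FoldAmyloid", "Aggrescan", "AmylPred")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = sorted({c for c in seq if c not in KYTE_DOOLITTLE})
    if bad:
        raise InputError(f"unknown residue letters {bad}")
    return seq


# ---------------------------------------------------------------------------
# Hydropathy and scale scans
# ---------------------------------------------------------------------------


def hydropathy_profile(sequence: str, window: int = 1) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy, one value per residue.

    The window is centred and truncated at the termini; window must be odd
    and no longer than the sequence.
    """
    seq = _validate_sequence(sequence)
    if window % 2 == 0 or window < 1 or window > len(seq):
        raise ParameterError("window must be odd, >= 1 and <= sequence length")
    values = np.array([KYTE_DOOLITTLE[c] for c in seq])
    half = window // 2
    out = np.empty(len(seq))
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


@dataclass(frozen=True)
class PredictorHits:
    """Hit positions (1-based) of one aggregation predictor on a sequence."""

    predictor: str
    positions: frozenset[int]
    sequence_length: int

    def __post_init__(self):
        bad = [p for p in self.positions if not 1 <= p <= self.sequence_length]
        if bad:
            raise InputError(f"hit positions {sorted(bad)} outside sequence bounds")

    def indicator(self) -> np.ndarray:
        ind = np.zeros(self.sequence_length, dtype=int)
        for p in self.positions:
            ind[p - 1] = 1
        return ind


def scale_scan(sequence: str, scale: dict[str, float], threshold: float,
               min_run: int = 1, mode: str = "above", window: int = 1,
               predictor: str = "custom") -> PredictorHits:
    """Positions whose (windowed) scale value passes a threshold in runs of
    >= ``min_run`` consecutive residues.

    ``mode='above'`` flags values strictly greater than the threshold,
    ``'below'`` strictly smaller. The optional centred window averages the
    scale before thresholding (truncated at the termini).
    """
    seq = _validate_sequence(sequence)
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    if mode not in ("above", "below"):
        raise ParameterError("mode must be 'above' or 'below'")
    missing = sorted({c for c in seq if c not in scale})
    if missing:
        raise InputError(f"scale lacks residues {missing}")
    values = np.array([scale[c] for c in seq], float)
    if window > 1:
        if window % 2 == 0:
            raise ParameterError("window must be odd")
        half = window // 2
        values = np.array([values[max(0, i - half):i + half + 1].mean()
                           for i in range(len(seq))])
    passing = values > threshold if mode == "above" else values < threshold
    return PredictorHits(predictor, _runs_to_hits(passing, min_run), len(seq))


def _runs_to_hits(passing: np.ndarray, min_run: int) -> frozenset[int]:
    hits: set[int] = set()
    run_start = None
    for i, ok in enumerate([*passing, False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start >= min_run:
                hits.update(range(run_start + 1, i + 1))
            run_start = None
    return frozenset(hits)


def packing_density_scan(sequence: str) -> PredictorHits:
    """Packing-density amyloidogenicity scan: 5-residue windowed expected
    packing density above 21.4 in runs of >= 5 residues."""
    return scale_scan(sequence, PACKING_DENSITY, PACKING_DENSITY_THRESHOLD,
                      min_run=5, window=5, predictor="FoldAmyloid")


def aggrescan_scan(sequence: str) -> PredictorHits:
    """AGGRESCAN-style hot spots: 5-residue windowed a3v (the a4v) above
    -0.02 in runs of >= 5 residues."""
    return scale_scan(sequence, AGGRESCAN_A3V, AGGRESCAN_THRESHOLD,
                      min_run=5, window=5, predictor="Aggrescan")


# ---------------------------------------------------------------------------
# External predictor output ingestion
# ---------------------------------------------------------------------------

#: Per-predictor hit rule applied to the parsed (position, value) table:
#: (threshold, min_run). AmylPred rows are (position, 0/1 consensus flag).
_PARSE_RULES = {"WALTZ": (0.0, 1), "TANGO": (0.0, 1),
                "FoldAmyloid": (21.4, 5), "Aggrescan": (-0.02, 1)}


def parse_predictor_output(path, predictor: str,
                           sequence_length: int) -> PredictorHits:
    """Read a two-column TSV of per-residue predictor output and apply the
    predictor's hit rule.

    Columns are ``position<TAB>value`` (1-based positions); for AmylPred the
    second column is the 0/1 consensus-hit flag. Lines starting with '#' and
    blank lines are skipped. Malformed rows raise :class:`ParseError` with
    the line number.
    """
    if predictor not in PREDICTOR_NAMES:
        raise InputError(f"unknown predictor {predictor!r}; expected one of "
                         f"{PREDICTOR_NAMES}")
    rows: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ParseError("expected 'position<TAB>value'", line=lineno)
            try:
                pos = int(parts[0])
                val = float(parts[1])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if not 1 <= pos <= sequence_length:
                raise ParseError(f"position {pos} outside sequence of length "
                                 f"{sequence_length}", line=lineno)
            rows.append((pos, val))
    values = np.zeros(sequence_length)
    seen = np.zeros(sequence_length, dtype=bool)
    for pos, val in rows:
        values[pos - 1] = val
        seen[pos - 1] = True
    if predictor == "AmylPred":
        passing = seen & (values > 0.5)
        return PredictorHits(predictor, _runs_to_hits(passing, 1), sequence_length)
    threshold, min_run = _PARSE_RULES[predictor]
    passing = seen & (values > threshold)
    return PredictorHits(predictor, _runs_to_hits(passing, min_run), sequence_length)


# ---------------------------------------------------------------------------
# Consensus amyloid score
# ---------------------------------------------------------------------------


@dataclass
class AmyloidScoreProfile:
    """0-5 per-residue consensus of the five aggregation predictors."""

    scores: np.ndarray                 # int, one per residue
    contributors: list[tuple[str, ...]]  # predictor names per residue
    sequence: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(1, len(self.sequence) + 1),
            "residue": list(self.sequence),
            "amyloid_score": self.scores,
            "predictors": [",".join(c) for c in self.contributors],
        })


def consensus_amyloid_score(hit_sets, sequence: str) -> AmyloidScoreProfile:
    """Per-residue count of predictors flagging the residue (0-5).

    Requires exactly the five canonical predictors, each exactly once.
    """
    seq = _validate_sequence(sequence)
    names = [h.predictor for h in hit_sets]
    if sorted(names) != sorted(PREDICTOR_NAMES):
        raise InputError(f"need exactly the predictors {PREDICTOR_NAMES}, "
                         f"got {names}")
    for h in hit_sets:
        if h.sequence_length != len(seq):
            raise InputError(f"{h.predictor} hits are for a sequence of length "
                             f"{h.sequence_length}, not {len(seq)}")
    scores = np.zeros(len(seq), dtype=int)
    contributors: list[tuple[str, ...]] = []
    for i in range(len(seq)):
        who = tuple(h.predictor for h in hit_sets if (i + 1) in h.positions)
        contributors.append(who)
        scores[i] = len(who)
    return AmyloidScoreProfile(scores=scores, contributors=contributors,
                               sequence=seq)


# ---------------------------------------------------------------------------
# Germline mutations
# ---------------------------------------------------------------------------


@dataclass
class MutationRecord:
    """One germline -> patient substitution with structural annotations."""

    position: int
    germline: str
    patient: str
    charge_change: int | None = None    # patient minus germline side-chain charge
    exposure: str | None = None         # 'surface' | 'buried'
    in_cdr: bool | None = None
    cavity_lining: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.germline == self.patient:
            raise ParameterError("a mutation must change the residue")

    @property
    def label(self) -> str:
        return f"{self.germline}{self.position}{self.patient}"


def list_mutations(patient_seq: str, germline_seq: str) -> list[MutationRecord]:
    """One record per position where patient and germline differ (equal
    lengths required; alignment is the caller's responsibility)."""
    p = _validate_sequence(patient_seq)
    g = _validate_sequence(germline_seq)
    if len(p) != len(g):
        raise InputError("sequences must be aligned to equal length")
    return [MutationRecord(position=i + 1, germline=ga, patient=pa)
            for i, (ga, pa) in enumerate(zip(g, p)) if ga != pa]


#: Neighbour-count burial proxy: C-alpha atoms of other residues within
#: this radius of the residue's C-beta (C-alpha for Gly); >= the threshold
#: counts as buried. Counting C-alphas keeps the proxy comparable between
#: full-atom and backbone-only models.
BURIAL_RADIUS = 10.0
BURIAL_NEIGHBOR_THRESHOLD = 12


def classify_mutation(record: MutationRecord, structure: AtomicModel,
                      cdr_ranges=(), cavity_linings=None,
                      chain: str | None = None) -> MutationRecord:
    """Annotate a mutation with charge change, burial, CDR membership and
    cavity lining.

    * charge change: side-chain formal charge at pH 7, patient minus germline.
    * exposure: neighbour-count proxy (C-alpha atoms of other residues
      within 10 A of the C-beta, or C-alpha for glycine; >= 12 counts as
      buried).
    * cdr_ranges: iterable of (start, end) inclusive residue ranges.
    * cavity_linings: mapping cavity label -> set of residue numbers (as
      produced by the cavity finder's polarity report).

    A residue missing from the structure yields a partial annotation with a
    warning instead of an error.
    """
    out = replace(record)
    out.charge_change = RESIDUE_CHARGE[record.patient] - RESIDUE_CHARGE[record.germline]
    out.in_cdr = any(lo <= record.position <= hi for lo, hi in cdr_ranges)
    if cavity_linings:
        out.cavity_lining = sorted(label for label, residues in cavity_linings.items()
                                   if record.position in residues)
    try:
        res = structure.residue(record.position, chain=chain)
    except InputError:
        out.warnings = [*record.warnings,
                        f"residue {record.position} missing from structure; "
                        "exposure not annotated"]
        return out
    anchor = res[res["name"] == "CB"]
    if anchor.empty:
        anchor = res[res["name"] == "CA"]
    if anchor.empty:
        out.warnings = [*record.warnings,
                        f"residue {record.position} has no CB/CA anchor"]
        return out
    center = anchor[["x", "y", "z"]].to_numpy(float)[0]
    heavy = structure.heavy().atoms
    others = heavy[(heavy["res_seq"] != record.position)
                   & (heavy["name"] == "CA")]
    d = np.linalg.norm(others[["x", "y", "z"]].to_numpy(float) - center, axis=1)
    n_neighbors = int((d <= BURIAL_RADIUS).sum())
    out.exposure = ("buried" if n_neighbors >= BURIAL_NEIGHBOR_THRESHOLD
                    else "surface")
    return out


def ordered_core_residue_count(core_range: tuple[int, int] = (15, 105)) -> int:
    """Number of residues in an inclusive residue range (default: the
    ordered fibril core Gly15-Thr105)."""
    lo, hi = core_range
    if hi < lo:
        raise ParameterError("range must be ordered")
    return hi - lo + 1
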