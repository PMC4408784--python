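"""Secondary-structure annotation and structure-signal quantification.

The binary classifier throughout is the per-position paired/unpaired state:
unpaired is the positive class, and a good probing profile gives unpaired
positions *higher* scores (SHAPE chemistry acylates flexible riboses).
AUC is computed by the Mann-Whitney rank formulation, i.e. the probability
that a random unpaired position outranks a random paired one, with ties
counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DataError, EvaluationError

_OPEN = "([{<"
_CLOSE = ")]}>"


@dataclass
class StructureAnnotation:
    """Per-position pairing state with optional ribose accessibility.

    ``paired[i-1]`` is True when position i is base-paired (canonical or
    noncanonical, as far as the source annotation encodes them).
    ``region`` is the inclusive 1-based interval used for evaluation
    (defaults to the whole molecule). ``accessibility`` is in Å² when
    present; evaluation then keeps only positions above the threshold.
    """

    rna_id: str
    paired: np.ndarray  # bool, length L
    accessibility: np.ndarray | None = None
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.paired = np.asarray(self.paired, dtype=bool)
        L = len(self.paired)
        if self.accessibility is not None:
            self.accessibility = np.asarray(self.accessibility, dtype=float)
            if len(self.accessibility) != L:
                raise DataError("accessibility length differs from structure length")
            if np.nanmin(self.accessibility) < 0:
                raise DataError("accessibility must be nonnegative")
        if self.region is None:
            self.region = (1, L)
        lo, hi = self.region
        if not (1 <= lo <= hi <= L):
            raise DataError(f"region {self.region} outside 1..{L}")

    @property
    def length(self) -> int:
        return len(self.paired)


@dataclass
class EvalConfig:
    """Filters applied before ROC/stratification.

    The accessibility threshold (Å², default 3) only bites when the
    annotation carries accessibility values — buried riboses cannot react
    regardless of pairing state and would pollute the negative class.
    """

    accessibility_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.accessibility_threshold < 0:
            raise DataError("accessibility threshold must be >= 0")


def parse_dotbracket(text: str, rna_id: str = "rna") -> StructureAnnotation:
    """Parse a dot-bracket string ((), [], {}, <> plus Aa/Bb/... pseudoknots)."""
    stacks: dict[str, list[int]] = {}
    paired = np.zeros(len(text), dtype=bool)
    for i, ch in enumerate(text):
        if ch in (".", "-", ","):
            continue
        if ch in _OPEN:
            stacks.setdefault(ch, []).append(i)
            paired[i] = True
        elif ch in _CLOSE:
            opener = _OPEN[_CLOSE.index(ch)]
            if not stacks.get(opener):
                raise DataError(f"unbalanced {ch!r} at position {i + 1}")
            stacks[opener].pop()
            paired[i] = True
        elif ch.isalpha():
            # pseudoknot letters: uppercase opens, lowercase closes
            if ch.isupper():
                stacks.setdefault(ch, []).append(i)
            else:
                if not stacks.get(ch.upper()):
                    raise DataError(f"unbalanced pseudoknot {ch!r} at position {i + 1}")
                stacks[ch.upper()].pop()
            paired[i] = True
        else:
            raise DataError(f"unexpected character {ch!r} at position {i + 1}")
    leftover = {k: v for k, v in stacks.items() if v}
    if leftover:
        k = next(iter(leftover))
        raise DataError(
            f"unbalanced {k!r}: {len(leftover[k])} unmatched opener(s)"
        )
    return StructureAnnotation(rna_id, paired)


def _read_dotbracket_file(path: str | Path) -> StructureAnnotation:
    rna_id = Path(path).stem
    structure = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith((">", "#", ";")):
                rna_id = line[1:].split()[0] or rna_id
                continue
            if set(line.upper()) <= set("ACGUTN"):
                continue  # sequence line
            structure = line
            break
    if structure is None:
        raise DataError(f"{path}: no dot-bracket line found")
    return parse_dotbracket(structure, rna_id)


def _read_ct_file(path: str | Path) -> StructureAnnotation:
    """Parse a CT file: columns index, base, prev, next, pairing partner, natural."""
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise DataError(f"{path}: empty CT file")
        try:
            L = int(header[0])
        except ValueError as exc:
            raise DataError(f"{path}: CT header does not start with a length") from exc
        rna_id = header[1] if len(header) > 1 else Path(path).stem
        paired = np.zeros(L, dtype=bool)
        expected = 1
        for lineno, line in enumerate(fh, 2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise DataError(f"{path} line {lineno}: CT row has {len(fields)} columns")
            idx, partner = int(fields[0]), int(fields[4])
            if idx != expected:
                raise DataError(
                    f"{path} line {lineno}: CT index {idx}, expected {expected}"
                )
            if partner < 0 or partner > L:
                raise DataError(f"{path} line {lineno}: partner {partner} out of range")
            paired[idx - 1] = partner != 0
            expected += 1
        if expected != L + 1:
            raise DataError(f"{path}: CT file has {expected - 1} rows, header says {L}")
    return StructureAnnotation(rna_id, paired)


def _read_pairing_tsv(path: str | Path) -> StructureAnnotation:
    """Plain per-position TSV: position, paired(0/1)[, accessibility].

    Accepted because dot-bracket/CT cannot encode every noncanonical pair a
    crystal structure shows; sources that tabulate pairing directly can be
    consumed as-is.
    """
    positions, flags, access = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not fields[0].isdigit():
                continue  # header
            positions.append(int(fields[0]))
            flags.append(int(fields[1]) != 0)
            if len(fields) > 2 and fields[2] != "":
                access.append(float(fields[2]))
    if positions != list(range(1, len(positions) + 1)):
        raise DataError(f"{path}: positions must be contiguous from 1")
    acc = np.array(access) if len(access) == len(positions) else None
    return StructureAnnotation(Path(path).stem, np.array(flags, dtype=bool), acc)


def parse_structure(path: str | Path, format: str | None = None) -> StructureAnnotation:
    """Read a structure annotation (``dotbracket``, ``ct`` or ``tsv``).

    With format=None the extension decides (.ct -> CT, .tsv -> TSV,
    otherwise dot-bracket).
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {".ct": "ct", ".tsv": "tsv"}.get(suffix, "dotbracket")
    fmt = format.lower()
    if fmt in ("dotbracket", "db", "dbn"):
        return _read_dotbracket_file(path)
    if fmt == "ct":
        return _read_ct_file(path)
    if fmt == "tsv":
        return _read_pairing_tsv(path)
    raise DataError(f"unknown structure format {format!r}")


def evaluation_mask(
    scores: np.ndarray, annotation: StructureAnnotation, config: EvalConfig
) -> np.ndarray:
    """Boolean mask of positions entering the evaluation: inside the region,
    accessible (when accessibility is supplied), and with a non-missing
    score — missing coverage is not evidence and is excluded, not imputed."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != annotation.length:
        raise DataError(
            f"score length {len(scores)} != structure length {annotation.length}"
        )
    lo, hi = annotation.region
    mask = np.zeros(annotation.length, dtype=bool)
    mask[lo - 1 : hi] = True
    mask &= ~np.isnan(scores)
    if annotation.accessibility is not None:
        mask &= annotation.accessibility > config.accessibility_threshold
    return mask


@dataclass
class AucResult:
    auc: float
    fpr: np.ndarray  # ROC x-coordinates
    tpr: np.ndarray  # ROC y-coordinates
    n_pos: int  # unpaired positions evaluated
    n_neg: int  # paired positions evaluated


def evaluate_auc(
    scores: np.ndarray,
    annotation: StructureAnnotation,
    config: EvalConfig | None = None,
) -> AucResult:
    """AUC of scores against the paired/unpaired classifier.

    AUC = P(score_unpaired > score_paired) + 0.5 * P(tie), computed from
    midranks; ROC points (one per distinct threshold, descending) are
    returned for plotting.
    """
    config = config or EvalConfig()
    scores = np.asarray(scores, dtype=float)
    mask = evaluation_mask(scores, annotation, config)
    s = scores[mask]
    unpaired = ~annotation.paired[mask]
    n_pos = int(unpaired.sum())
    n_neg = int((~unpaired).sum())
    if n_pos == 0 or n_neg == 0:
        empty = "unpaired (positive)" if n_pos == 0 else "paired (negative)"
        raise EvaluationError(
            f"cannot evaluate AUC: the {empty} class is empty after filtering "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    ranks = stats.rankdata(s)  # midranks handle ties
    auc = (ranks[unpaired].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # ROC points: sweep thresholds from high to low
    order = np.argsort(-s, kind="mergesort")
    sorted_scores = s[order]
    tp = np.cumsum(unpaired[order])
    fp = np.cumsum(~unpaired[order])
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return AucResult(float(auc), fpr, tpr, n_pos, n_neg)


def spearman_correlation(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Spearman rank correlation with pairwise deletion of missing positions."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if len(a) != len(b):
        raise DataError(f"profile length mismatch: {len(a)} vs {len(b)}")
    keep = ~(np.isnan(a) | np.isnan(b))
    if keep.sum() < 3:
        raise EvaluationError(
            f"only {int(keep.sum())} shared positions; need at least 3"
        )
    rho = stats.spearmanr(a[keep], b[keep]).statistic
    return float(rho)


@dataclass
class StratifiedScores:
    """Reactivities split by pairing state, with boxplot-ready summaries."""

    unpaired: np.ndarray
    paired: np.ndarray
    summary: dict = field(default_factory=dict)


def _five_number(x: np.ndarray) -> dict[str, float]:
    qs = np.percentile(x, [0, 25, 50, 75, 100])
    return dict(zip(("min", "q1", "median", "q3", "max"), map(float, qs)))


def stratify_reactivity(
    scores: np.ndarray,
    annotation: StructureAnnotation,
    config: EvalConfig | None = None,
) -> StratifiedScores:
    """Split filtered scores into paired/unpaired strata with 5-number summaries."""
    config = config or EvalConfig()
    scores = np.asarray(scores, dtype=float)
    mask = evaluation_mask(scores, annotation, config)
    s = scores[mask]
    unp = s[~annotation.paired[mask]]
    par = s[annotation.paired[mask]]
    if len(unp) == 0 or len(par) == 0:
        empty = "unpaired" if len(unp) == 0 else "paired"
        raise EvaluationError(f"cannot stratify: the {empty} stratum is empty")
    return StratifiedScores(
        unp, par, {"unpaired": _five_number(unp), "paired": _five_number(par)}
    )


def write_roc_tsv(path, result: AucResult) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in zip(result.fpr, result.tpr):
            fh.write(f"{x:.6g}\t{y:.6g}\n")
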