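"""Synthetic probing-experiment generator.

Emulates a selection-based SHAPE experiment at the aligned-fragment level
(no sequence simulation, no aligner errors):

1. each RNA molecule acquires chemical adducts independently per position,
   at a higher rate for unpaired than for paired positions (the single-hit
   regime is reached by keeping the rates small, not by truncation);
2. reverse transcription starts at a priming position drawn from a biased
   priming distribution and walks toward the 5' end; at each extension step
   it can drop off (geometric background) or be blocked by an adduct at the
   next position (unless it reads through); reaching position 1 yields a
   run-off fragment;
3. fragments shorter than a size cutoff are discarded (library size
   selection);
4. the selection arm keeps adduct-terminated cDNAs with high probability
   while background terminations only leak through rarely
   (biotin-streptavidin capture with imperfect washing).

Termination convention: termination means failing to extend into the next
target position, so a blocking adduct at position i gives a fragment left
end of i + 1 and drop-off while extending into j gives left end j + 1.
Under this convention, with drop-off rate d and priming at p,
P(left = j) = d * (1 - d)^(p - j) for 1 < j <= p and
P(run-off) = (1 - d)^(p - 1), and the downstream stop-counting rule
(left - 1) recovers the adduct position exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError
from .fragments import FragmentRecord, write_fragments

_CHUNK = 8192  # molecules per vectorized block, bounds transient memory

ARMS = ("control", "probed", "selected")


@dataclass
class SimulationConfig:
    """Parameters of one simulated probing experiment on one RNA.

    Default rates put the probed arm in the regime the chemistry aims for:
    adduct formation an order of magnitude more likely at flexible
    (unpaired) riboses, a small per-nucleotide RT drop-off background, and
    a selection step that is efficient but leaky.
    """

    paired: np.ndarray  # bool vector, length L; True = base-paired
    n_molecules: int = 50_000
    mod_rate_unpaired: float = 0.02
    mod_rate_paired: float = 0.002
    dropoff_rate: float = 0.002
    readthrough_prob: float = 0.0
    priming_weights: np.ndarray | None = None  # length L, unnormalized
    min_fragment_len: int = 20
    selection_keep: float = 0.8
    selection_leak: float = 0.02
    seed: int = 0
    rna_id: str = "rna"

    def __post_init__(self) -> None:
        self.paired = np.asarray(self.paired, dtype=bool)
        L = len(self.paired)
        if L == 0:
            raise ConfigurationError("structure vector is empty")
        if self.n_molecules <= 0:
            raise ConfigurationError("n_molecules must be positive")
        for name in ("mod_rate_unpaired", "mod_rate_paired"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.mod_rate_unpaired < self.mod_rate_paired:
            raise ConfigurationError(
                "mod_rate_unpaired must be >= mod_rate_paired"
            )
        if not (0.0 <= self.dropoff_rate < 1.0):
            raise ConfigurationError(f"dropoff_rate={self.dropoff_rate} outside [0, 1)")
        if not (0.0 <= self.readthrough_prob < 1.0):
            raise ConfigurationError(
                f"readthrough_prob={self.readthrough_prob} outside [0, 1)"
            )
        if not (0.0 < self.selection_keep <= 1.0):
            raise ConfigurationError(f"selection_keep={self.selection_keep} outside (0, 1]")
        if not (0.0 <= self.selection_leak < 1.0):
            raise ConfigurationError(f"selection_leak={self.selection_leak} outside [0, 1)")
        if self.min_fragment_len < 1:
            raise ConfigurationError("min_fragment_len must be positive")
        if L < self.min_fragment_len:
            raise ConfigurationError(
                f"L={L} shorter than min_fragment_len={self.min_fragment_len}"
            )
        if self.priming_weights is not None:
            w = np.asarray(self.priming_weights, dtype=float)
            if len(w) != L:
                raise ConfigurationError("priming_weights length differs from L")
            if (w < 0).any() or w.sum() <= 0:
                raise ConfigurationError(
                    "priming_weights must be nonnegative with a positive sum"
                )
            self.priming_weights = w

    @property
    def length(self) -> int:
        return len(self.paired)

    def modification_rates(self) -> np.ndarray:
        """Per-position adduct probability implied by the structure."""
        return np.where(self.paired, self.mod_rate_paired, self.mod_rate_unpaired)

    def normalized_priming(self) -> np.ndarray:
        w = self.priming_weights
        if w is None:
            w = default_priming_weights(self.length)
        return w / w.sum()


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    modification_rate: np.ndarray  # per-position adduct probability
    expected_stop_fraction: np.ndarray  # analytic stop probability per position
    expected_runoff_fraction: float
    labels: np.ndarray  # copy of the paired vector


def default_priming_weights(
    L: int, rng: np.random.Generator | None = None, roughness: float = 0.0
) -> np.ndarray:
    """Mildly 3'-skewed priming distribution (weight ramps 1 -> 2 along the
    molecule), optionally multiplied by lognormal per-position roughness to
    emulate the strong site-to-site bias of random priming."""
    w = 1.0 + np.arange(1, L + 1) / L
    if roughness > 0:
        if rng is None:
            raise ConfigurationError("roughness > 0 requires an rng")
        w = w * rng.lognormal(mean=0.0, sigma=roughness, size=L)
    return w


def synthetic_structure(
    L: int,
    frac_unpaired: float = 0.45,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, str]:
    """Generate a valid nested secondary structure of length L.

    Built as a chain of hairpins (stem 3-8 bp, loop 3-8 nt) separated by
    single-stranded linkers sized adaptively so the overall unpaired
    fraction tracks ``frac_unpaired``. Returns (paired vector, dot-bracket).
    """
    if not (0.0 < frac_unpaired < 1.0):
        raise ConfigurationError("frac_unpaired must be in (0, 1)")
    rng = rng or np.random.default_rng(0)
    parts: list[str] = []
    n_paired = n_unpaired = 0
    pos = 0
    while pos < L:
        s = int(rng.integers(3, 9))
        loop = int(rng.integers(3, 9))
        # linker that keeps the running unpaired fraction on target
        target_unpaired = (n_paired + 2 * s) * frac_unpaired / (1.0 - frac_unpaired)
        linker = max(0, round(target_unpaired - n_unpaired - loop))
        block = "." * linker + "(" * s + "." * loop + ")" * s
        if pos + len(block) > L:
            parts.append("." * (L - pos))
            pos = L
            break
        parts.append(block)
        n_paired += 2 * s
        n_unpaired += linker + loop
        pos += len(block)
    db = "".join(parts)
    paired = np.fromiter((c != "." for c in db), dtype=bool, count=L)
    return paired, db


def simulate_modifications(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-molecule adduct sets: boolean matrix (n_molecules, L).

    Each position is modified independently with the structure-dependent
    rate; the expected adduct count per molecule is the sum of the rates.
    """
    rates = config.modification_rates()
    n, L = config.n_molecules, config.length
    mods = np.empty((n, L), dtype=bool)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        mods[start:stop] = rng.random((stop - start, L)) < rates
    return mods


def simulate_fragments(
    molecules: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[FragmentRecord]:
    """Reverse-transcribe each molecule into exactly one fragment.

    Priming position p is drawn from the priming distribution; the RT walk
    terminates by adduct block (probability 1 - readthrough_prob per
    encountered adduct) or drop-off (per-step probability dropoff_rate);
    completing the walk gives a run-off fragment with left = 1. No size
    filter is applied here (see :func:`size_filter`), so the output length
    always equals the number of molecules.
    """
    molecules = np.asarray(molecules, dtype=bool)
    n, L = molecules.shape
    if L != config.length:
        raise DataError("molecule matrix width differs from structure length")
    pw = config.normalized_priming()
    p = rng.choice(L, size=n, p=pw) + 1  # 1-based priming positions

    # adduct block candidates: modified positions that actually arrest RT
    rows, cols = np.nonzero(molecules)
    if config.readthrough_prob > 0 and len(rows):
        blocked = rng.random(len(rows)) >= config.readthrough_prob
        rows, cols = rows[blocked], cols[blocked]
    mod_pos = cols + 1
    # only adducts strictly below the priming position are ever encountered
    seen = mod_pos <= p[rows] - 1
    mod_target = np.zeros(n, dtype=np.int64)
    np.maximum.at(mod_target, rows[seen], mod_pos[seen])

    if config.dropoff_rate > 0:
        g = rng.geometric(config.dropoff_rate, size=n)
        drop_target = p - g  # position the failed extension was entering
        drop_target[drop_target < 1] = 0
    else:
        drop_target = np.zeros(n, dtype=np.int64)

    # the first stop on the walk is the highest candidate below p;
    # at a tie the adduct is encountered before the drop-off draw
    target = np.maximum(mod_target, drop_target)
    left = np.where(target >= 1, target + 1, 1)
    is_mod = (mod_target >= 1) & (mod_target >= drop_target)
    causes = np.where(target < 1, "runoff", np.where(is_mod, "modification", "dropoff"))
    return [
        FragmentRecord(config.rna_id, int(l), int(r), str(c))
        for l, r, c in zip(left, p, causes)
    ]


def size_filter(
    fragments: list[FragmentRecord], min_fragment_len: int
) -> tuple[list[FragmentRecord], int]:
    """Discard fragments shorter than the library size cutoff.

    Returns (kept fragments, number discarded)."""
    kept = [f for f in fragments if f.length >= min_fragment_len]
    return kept, len(fragments) - len(kept)


def apply_selection(
    fragments: list[FragmentRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[FragmentRecord]:
    """Biotin-streptavidin selection: adduct-terminated cDNAs are retained
    with probability selection_keep, everything else (drop-off and run-off)
    leaks through with probability selection_leak."""
    if any(f.cause is None for f in fragments):
        raise DataError("apply_selection requires cause-labelled fragments")
    keep_prob = np.where(
        np.array([f.cause == "modification" for f in fragments]),
        config.selection_keep,
        config.selection_leak,
    )
    keep = rng.random(len(fragments)) < keep_prob
    return [f for f, k in zip(fragments, keep) if k]


def expected_stop_fraction(config: SimulationConfig) -> tuple[np.ndarray, float]:
    """Closed-form per-position stop probability, the simulation's analytic twin.

    For the walk from priming position p, the extension into position i
    survives with probability s_i = (1 - m_i*(1 - r)) * (1 - d); the stop
    probability at i, marginalized over the priming distribution, is
    (1 - s_i) * sum_{p > i} w_p * prod_{k=i+1}^{p-1} s_k, and run-off is
    sum_p w_p * prod_{k=1}^{p-1} s_k. Returns (stop vector indexed by the
    reported stop position i, run-off probability); no size filter or
    selection is applied.
    """
    L = config.length
    m = config.modification_rates()
    surv = (1.0 - m * (1.0 - config.readthrough_prob)) * (1.0 - config.dropoff_rate)
    w = config.normalized_priming()
    # cum[j] = prod_{k=1..j} surv_k, cum[0] = 1
    cum = np.concatenate([[1.0], np.cumprod(surv)])
    wc = w * cum[:L]  # w_p * prod_{k=1..p-1} surv_k, index p-1
    suffix = np.concatenate([np.cumsum(wc[::-1])[::-1], [0.0]])  # sum_{p>=i+1}
    stops = (1.0 - surv) * suffix[1:] / cum[1:]
    runoff = float(wc.sum())
    return stops, runoff


def ground_truth(config: SimulationConfig) -> GroundTruth:
    stops, runoff = expected_stop_fraction(config)
    return GroundTruth(
        modification_rate=config.modification_rates(),
        expected_stop_fraction=stops,
        expected_runoff_fraction=runoff,
        labels=config.paired.copy(),
    )


@dataclass
class ExperimentResult:
    """Three-arm experiment (no-reagent control, probed, probed+selected)."""

    arms: dict[str, list[FragmentRecord]]
    config: SimulationConfig
    truth: GroundTruth
    spike_truth: dict[str, GroundTruth] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)


def simulate_experiment(
    config: SimulationConfig,
    spikes: dict[str, SimulationConfig] | None = None,
    seed: int | None = None,
) -> ExperimentResult:
    """Run the three arms of a selection experiment on one RNA.

    The control arm re-runs the generative model with both modification
    rates at zero; the selected arm applies selection to the *same* probed
    fragments, so selection diagnostics compare like with like. Spike-in
    RNAs (extra configs keyed by rna_id, e.g. a never-modified spike) are
    appended to the probed arm and ride through the same selection step.
    One seed drives everything; per-arm substreams are spawned
    deterministically.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    keys = ["priming", "control", "probed", "selection"] + sorted(spikes or {})
    streams = dict(zip(keys, ss.spawn(len(keys))))

    if config.priming_weights is None:
        config = replace(
            config,
            priming_weights=default_priming_weights(
                config.length,
                np.random.default_rng(streams["priming"]),
                roughness=0.5,
            ),
        )

    stats: dict[str, dict] = {}

    def run_arm(cfg: SimulationConfig, rng: np.random.Generator) -> list[FragmentRecord]:
        mods = simulate_modifications(cfg, rng)
        return simulate_fragments(mods, cfg, rng)

    control_cfg = replace(config, mod_rate_unpaired=0.0, mod_rate_paired=0.0)
    control = run_arm(control_cfg, np.random.default_rng(streams["control"]))
    probed = run_arm(config, np.random.default_rng(streams["probed"]))

    spike_truths: dict[str, GroundTruth] = {}
    for rna_id in sorted(spikes or {}):
        cfg = spikes[rna_id]
        if cfg.rna_id != rna_id:
            cfg = replace(cfg, rna_id=rna_id)
        if cfg.priming_weights is None:
            cfg = replace(cfg, priming_weights=default_priming_weights(cfg.length))
        probed += run_arm(cfg, np.random.default_rng(streams[rna_id]))
        spike_truths[rna_id] = ground_truth(cfg)

    selected = apply_selection(
        probed, config, np.random.default_rng(streams["selection"])
    )

    arms: dict[str, list[FragmentRecord]] = {}
    for name, frags in (("control", control), ("probed", probed), ("selected", selected)):
        kept, n_short = size_filter(frags, config.min_fragment_len)
        arms[name] = kept
        stats[name] = {
            "n_fragments": len(frags),
            "n_discarded_short": n_short,
            "n_kept": len(kept),
        }

    return ExperimentResult(
        arms=arms,
        config=config,
        truth=ground_truth(config),
        spike_truth=spike_truths,
        stats=stats,
    )


def write_ground_truth_tsv(path, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        fh.write("position\tmodification_rate\tpaired_flag\n")
        for i, (m, pf) in enumerate(zip(truth.modification_rate, truth.labels), 1):
            fh.write(f"{i}\t{m:.6g}\t{int(pf)}\n")


def write_dotbracket(path, dotbracket: str, rna_id: str = "rna") -> None:
    with open(path, "w") as fh:
        fh.write(f">{rna_id}\n{dotbracket}\n")


def write_experiment(result: ExperimentResult, outdir: str | Path) -> None:
    """Write the three arms as BED6 plus the ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frags in result.arms.items():
        write_fragments(frags, outdir / f"{name}.bed", format="bed")
    write_ground_truth_tsv(outdir / "ground_truth.tsv", result.truth)
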