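"""Synthetic inputs for every pipeline stage.

Generates random genomes, mutation-accumulation call sets with a specified
96-class context spectrum (plus optional injected filter-test artifacts),
Luria-Delbrueck fluctuation assays, and noisy divergence time series.  All
generators take an explicit integer seed; there is no global random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import MutationCall, ReferenceGenome
from .rates import MALine
from .spectra import CLASS_LABELS, SUBSTITUTIONS

_BASES = np.array(list("ACGT"))
_BASE_CODE = {b: i for i, b in enumerate("ACGT")}
_SV_SOURCES = ("lumpy", "cnvnator", "breakdancer")

#: sequencing depth of clean simulated calls is Poisson with this mean, so
#: clean calls essentially never trip the depth-4 quality filter
CLEAN_DEPTH_MEAN = 150
CLEAN_QUAL = 60.0


@dataclass
class MATruth:
    """Ground-truth parameters of a simulated MA experiment."""

    snm_rate: float  # per site per generation
    sim_rate: float = 0.0  # per site per generation
    svm_rate: float = 0.0  # per genome per generation
    spectrum_weights: Optional[np.ndarray] = None  # 96 weights, sum 1
    n_lines: int = 25
    generations_per_line: float = 1500.0
    genome_length: int = 0  # informational; the genome passed in rules

    def __post_init__(self):
        if min(self.snm_rate, self.sim_rate, self.svm_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.n_lines < 1:
            raise ValueError("need at least one line")
        if self.spectrum_weights is None:
            self.spectrum_weights = np.full(96, 1.0 / 96)
        self.spectrum_weights = np.asarray(self.spectrum_weights, dtype=float)
        if self.spectrum_weights.shape != (96,):
            raise ValueError("spectrum_weights must have 96 entries")
        if (self.spectrum_weights < 0).any():
            raise ValueError("spectrum_weights must be non-negative")
        total = self.spectrum_weights.sum()
        if total <= 0:
            raise ValueError("spectrum_weights must not be all zero")
        self.spectrum_weights = self.spectrum_weights / total


@dataclass
class ArtifactPlan:
    """False calls to inject for exercising the filter stage.

    n_shared_snm: loci given an identical false SNM in ``shared_in_lines``
    lines each (caught by the consensus filter when shared_in_lines exceeds
    the consensus limit).
    n_lowdepth: calls injected with depth < 4 (caught by the quality filter).
    n_outlier_lines: leading lines whose true mutation counts are inflated
    by ``inflation_factor`` (caught by Z-score outlier exclusion).
    """

    n_shared_snm: int = 0
    shared_in_lines: int = 3
    n_lowdepth: int = 0
    n_outlier_lines: int = 0
    inflation_factor: float = 10.0

    def __post_init__(self):
        if min(self.n_shared_snm, self.shared_in_lines, self.n_lowdepth,
               self.n_outlier_lines) < 0:
            raise ValueError("artifact counts must be >= 0")


@dataclass
class DivergenceSeries:
    """Genomic divergence (sum of derived allele frequencies) over time."""

    generations: np.ndarray
    divergence: np.ndarray

    def __post_init__(self):
        self.generations = np.asarray(self.generations, dtype=float)
        self.divergence = np.asarray(self.divergence, dtype=float)
        if self.generations.shape != self.divergence.shape:
            raise ValueError("generations and divergence must align")
        if self.generations.size and (np.diff(self.generations) <= 0).any():
            raise ValueError("generations must be strictly increasing")
        if (self.divergence < 0).any():
            raise ValueError("divergence must be non-negative")


@dataclass
class FluctuationAssay:
    """Mutant counts across parallel cultures of one fluctuation test."""

    n_final: float  # cells per culture at plating (Nt)
    counts: np.ndarray  # observed mutant count per selective culture
    label: str = ""

    def __post_init__(self):
        if self.n_final < 1:
            raise ValueError("n_final must be >= 1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def gen_genome(length: int, gc_fraction: float = 0.5, seed: int = 0,
               name: str = "chr1") -> ReferenceGenome:
    """I.i.d. random genome with the requested GC content."""
    if length < 3:
        raise ValueError("genome must be at least 3 bases")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = "".join(_BASES[codes])
    return ReferenceGenome({name: seq})


# ---------------------------------------------------------------------------
# Context-aware site index
# ---------------------------------------------------------------------------

# 32 collapsed trinucleotide contexts: 5' flank (4) x focal pyrimidine (2)
# x 3' flank (4), after strand collapsing.  Each 96-class maps to one
# context plus an alt base.


def _class_context_and_alt(class_index: int) -> tuple[int, str, str]:
    """Map a 96-class index to (context id, pyrimidine ref, pyrimidine alt)."""
    sub = class_index // 16
    flank = class_index % 16
    f5, f3 = flank // 4, flank % 4
    ref, alt = SUBSTITUTIONS[sub]
    fbit = 1 if ref == "T" else 0
    return f5 * 8 + fbit * 4 + f3, ref, alt


class ContextIndex:
    """Per-context lists of mutable genome sites, for spectrum-true placement.

    Sites are interior positions (both flanks present) whose trinucleotide is
    pure ACGT.  Context ids are strand-collapsed, so a site whose focal base
    is a purine belongs to the context of its reverse complement.
    """

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.chrom_of: list[str] = []
        offsets = {}
        pos_blocks = []
        ctx_blocks = []
        offset = 0
        for name, seq in genome.items():
            codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            lut = np.full(256, -1, dtype=np.int8)
            for b, c in _BASE_CODE.items():
                lut[ord(b)] = c
            codes = lut[codes].astype(np.int64)
            if len(codes) < 3:
                continue
            c5 = codes[:-2]
            cf = codes[1:-1]
            c3 = codes[2:]
            valid = (c5 >= 0) & (cf >= 0) & (c3 >= 0)
            pur = (cf == 0) | (cf == 2)  # A or G at the focal site
            f5 = np.where(pur, 3 - c3, c5)
            fo = np.where(pur, 3 - cf, cf)  # collapses to C (1) or T (3)
            f3 = np.where(pur, 3 - c5, c3)
            ctx = f5 * 8 + (fo == 3).astype(np.int64) * 4 + f3
            pos = np.nonzero(valid)[0] + 1  # 0-based focal position
            pos_blocks.append(pos + offset)
            ctx_blocks.append(ctx[valid])
            offsets[name] = offset
            self.chrom_of.append(name)
            offset += len(seq)
        self._offsets = offsets
        self._lengths = {n: len(s) for n, s in genome.items()}
        all_pos = np.concatenate(pos_blocks) if pos_blocks else np.empty(0, int)
        all_ctx = np.concatenate(ctx_blocks) if ctx_blocks else np.empty(0, int)
        order = np.argsort(all_ctx, kind="stable")
        sorted_pos = all_pos[order]
        sorted_ctx = all_ctx[order]
        bounds = np.searchsorted(sorted_ctx, np.arange(33))
        self.sites_by_context: list[np.ndarray] = [
            sorted_pos[bounds[i]: bounds[i + 1]] for i in range(32)
        ]
        self.n_callable = int(all_pos.size)

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Global 0-based index -> (chrom, 1-based position)."""
        for name in reversed(self.chrom_of):
            off = self._offsets[name]
            if global_pos >= off:
                return name, global_pos - off + 1
        raise IndexError(global_pos)

    def base_at(self, global_pos: int) -> str:
        chrom, pos = self.locate(global_pos)
        return self.genome[chrom][pos - 1]

    def class_weights_available(self, weights: np.ndarray) -> np.ndarray:
        """Zero out classes with no matching genomic site; renormalize."""
        avail = np.array(
            [len(self.sites_by_context[_class_context_and_alt(i)[0]]) > 0
             for i in range(96)]
        )
        if not avail.all() and (weights[~avail] > 0).any():
            warnings.warn(
                "spectrum weight positive for a context absent from the "
                "genome; renormalizing over available contexts"
            )
        w = np.where(avail, weights, 0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError("no spectrum class has available genomic sites")
        return w / total


_COMP = str.maketrans("ACGT", "TGCA")


def _place_snm(index: ContextIndex, class_index: int, rng,
               used: set) -> Optional[tuple[str, int, str, str]]:
    """Pick an unused site matching a 96-class; return (chrom,pos,ref,alt)."""
    ctx, pref, palt = _class_context_and_alt(class_index)
    sites = index.sites_by_context[ctx]
    if len(sites) == 0:
        return None
    for _ in range(100):
        gpos = int(sites[rng.integers(len(sites))])
        if gpos in used:
            continue
        used.add(gpos)
        chrom, pos = index.locate(gpos)
        ref = index.genome[chrom][pos - 1]
        alt = palt if ref == pref else palt.translate(_COMP)
        return chrom, pos, ref, alt
    return None  # pathologically saturated context


def simulate_ma(
    truth: MATruth,
    genome: ReferenceGenome,
    artifact_plan: Optional[ArtifactPlan] = None,
    seed: int = 0,
    progenitor_id: str = "P0",
) -> tuple[list[MutationCall], list[MALine]]:
    """Simulate per-line mutation calls of one MA experiment.

    Per line, SNM and SIM counts are Poisson with mean rate * G * n (n =
    interior callable sites) and SV counts Poisson with mean rate * G.
    SNMs land on sites whose reference trinucleotide context is drawn
    proportional to the truth spectrum (restricted to contexts present in
    the genome); sites are used at most once per line.  Clean calls carry
    depth ~ Poisson(150) and qual 60 so they pass the default quality
    filters; artifacts are appended with identifying ``ARTIFACT`` tags.
    """
    plan = artifact_plan or ArtifactPlan()
    rng = np.random.default_rng(seed)
    index = ContextIndex(genome)
    n_sites = index.n_callable
    weights = index.class_weights_available(truth.spectrum_weights)
    genome_names = list(genome)

    calls: list[MutationCall] = []
    lines: list[MALine] = []
    G = truth.generations_per_line

    def _depth() -> int:
        return int(max(4, rng.poisson(CLEAN_DEPTH_MEAN)))

    for i in range(truth.n_lines):
        line_id = f"{progenitor_id}-L{i + 1:03d}"
        lines.append(
            MALine(
                line_id=line_id,
                progenitor_id=progenitor_id,
                generations=G,
                covered_sites=n_sites,
            )
        )
        inflate = (
            plan.inflation_factor if i < plan.n_outlier_lines else 1.0
        )
        used: set[int] = set()

        n_snm = rng.poisson(truth.snm_rate * G * n_sites * inflate)
        class_counts = rng.multinomial(n_snm, weights)
        for ci in np.nonzero(class_counts)[0]:
            for _ in range(class_counts[ci]):
                placed = _place_snm(index, int(ci), rng, used)
                if placed is None:
                    continue
                chrom, pos, ref, alt = placed
                calls.append(
                    MutationCall(
                        line_id=line_id, chrom=chrom, pos=pos,
                        ref=ref, alt=alt, mclass="SNM",
                        depth=_depth(), qual=CLEAN_QUAL,
                    )
                )

        n_sim = rng.poisson(truth.sim_rate * G * n_sites * inflate)
        for _ in range(n_sim):
            chrom = genome_names[rng.integers(len(genome_names))]
            seq = genome[chrom]
            size = int(rng.integers(1, 5))
            is_del = bool(rng.integers(2))
            if is_del:
                pos = int(rng.integers(2, len(seq) - size))
                ref = seq[pos - 1: pos + size]
                alt = ref[0]
            else:
                pos = int(rng.integers(2, len(seq) - 1))
                ref = seq[pos - 1]
                alt = ref + "".join(_BASES[rng.integers(0, 4, size)])
            calls.append(
                MutationCall(
                    line_id=line_id, chrom=chrom, pos=pos,
                    ref=ref, alt=alt, mclass="SIM",
                    depth=_depth(), qual=CLEAN_QUAL,
                )
            )

        n_sv = rng.poisson(truth.svm_rate * G * inflate)
        for _ in range(n_sv):
            chrom = genome_names[rng.integers(len(genome_names))]
            seq = genome[chrom]
            length = int(rng.integers(100, max(101, min(10000, len(seq) // 2))))
            start = int(rng.integers(1, max(2, len(seq) - length)))
            sv_type = ("DEL", "DUP", "INV", "INS")[rng.integers(4)]
            calls.append(
                MutationCall(
                    line_id=line_id, chrom=chrom, pos=start,
                    ref="N", alt=f"<{sv_type}>", mclass="SV",
                    depth=_depth(), qual=CLEAN_QUAL,
                    sv_type=sv_type, sv_start=start,
                    sv_end=start + length - 1,
                    source=_SV_SOURCES[rng.integers(len(_SV_SOURCES))],
                )
            )

    # --- injected artifacts -------------------------------------------------
    line_ids = [ln.line_id for ln in lines]
    k = min(plan.shared_in_lines, len(line_ids))
    for _ in range(plan.n_shared_snm):
        placed = _place_snm(index, int(rng.integers(96)), rng, set())
        if placed is None:
            continue
        chrom, pos, ref, alt = placed
        for line_id in line_ids[:k]:
            calls.append(
                MutationCall(
                    line_id=line_id, chrom=chrom, pos=pos,
                    ref=ref, alt=alt, mclass="SNM",
                    depth=_depth(), qual=CLEAN_QUAL,
                    info={"ARTIFACT": "shared"},
                )
            )
    for j in range(plan.n_lowdepth):
        placed = _place_snm(index, int(rng.integers(96)), rng, set())
        if placed is None:
            continue
        chrom, pos, ref, alt = placed
        calls.append(
            MutationCall(
                line_id=line_ids[j % len(line_ids)], chrom=chrom, pos=pos,
                ref=ref, alt=alt, mclass="SNM",
                depth=int(rng.integers(0, 4)), qual=CLEAN_QUAL,
                info={"ARTIFACT": "lowdepth"},
            )
        )
    return calls, lines


def simulate_fluctuation(
    mu_per_division: float,
    n_final: float,
    n_cultures: int,
    seed: int = 0,
    label: str = "",
) -> FluctuationAssay:
    """Simulate mutant counts of parallel cultures under the Lea-Coulson model.

    Mutation events per culture are Poisson(m) with m = mu * Nt; each
    event founds a clone whose final size S satisfies P(S >= s) = 1/s
    (S = ceil(1/U) - 1 with U uniform on (0, 1], zero-size draws discarded),
    capped at Nt.  The observed mutant count is the sum of clone sizes.
    """
    if not 0 <= mu_per_division < 1:
        raise ValueError("mu_per_division must be in [0, 1)")
    if n_final < 2:
        raise ValueError("n_final must be >= 2")
    rng = np.random.default_rng(seed)
    m = mu_per_division * n_final
    events = rng.poisson(m, size=n_cultures)
    total = int(events.sum())
    sizes = np.zeros(total, dtype=np.int64)
    todo = np.arange(total)
    while todo.size:
        u = rng.random(todo.size)  # uniform [0, 1); 1-u is in (0, 1]
        s = np.ceil(1.0 / (1.0 - u)) - 1
        sizes[todo] = s.astype(np.int64)
        todo = todo[sizes[todo] == 0]  # discard size-0 draws, redraw
    sizes = np.minimum(sizes, int(n_final))
    owner = np.repeat(np.arange(n_cultures), events)
    counts = np.bincount(owner, weights=sizes, minlength=n_cultures)
    return FluctuationAssay(
        n_final=n_final, counts=counts.astype(np.int64), label=label
    )


def simulate_divergence(
    slope: float,
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DivergenceSeries:
    """Linear divergence through the origin with truncated Gaussian noise."""
    if slope < 0:
        raise ValueError("slope must be >= 0")
    x = np.asarray(timepoints, dtype=float)
    if x.size > 1 and (np.diff(x) <= 0).any():
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0
    y = np.maximum(0.0, slope * x + noise)
    return DivergenceSeries(generations=x, divergence=y)
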