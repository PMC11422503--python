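"""Completeness-guided assembly degradation: remove random contiguous blocks from FASTA.

Emulates the incompleteness of metagenome-assembled genomes by deleting a
target proportion of each assembly as contiguous sequence blocks. The
removal budget round((1 - completeness) * total_length) is split across
blocks by uniform stick-breaking; each block lands uniformly on a contig
chosen proportionally to its length. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix_io import CompletenessTable, write_completeness
from .pansim import draw_completeness

__all__ = [
    "DegradationPlan",
    "plan_degradation",
    "apply_degradation",
    "degrade_collection",
]

FASTA_SUFFIXES = (".fa", ".fasta", ".fna")


@dataclass
class DegradationPlan:
    """Removal intervals for one assembly, reproducible from its seed."""

    target_completeness: float
    intervals: list[tuple[str, int, int]]  # (contig id, start, end), half-open
    contig_lengths: dict[str, int]
    seed: int
    shrunk_blocks: int = 0

    def __post_init__(self) -> None:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in self.intervals:
            if contig not in self.contig_lengths:
                raise ValueError(f"interval on unknown contig {contig!r}")
            if not 0 <= start < end <= self.contig_lengths[contig]:
                raise ValueError(
                    f"interval [{start}, {end}) outside contig {contig!r} "
                    f"(length {self.contig_lengths[contig]})"
                )
            by_contig.setdefault(contig, []).append((start, end))
        for contig, ivals in by_contig.items():
            ivals.sort()
            for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping removal intervals on {contig!r}")

    @property
    def total_length(self) -> int:
        return sum(self.contig_lengths.values())

    @property
    def removed_length(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    @property
    def realized_completeness(self) -> float:
        total = self.total_length
        return (total - self.removed_length) / total


def _split_budget(budget: int, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform stick-breaking of the removal budget into integer block lengths.

    Rounding is applied to the cumulative cuts so the block lengths sum to
    the budget exactly; zero-length fragments are dropped.
    """
    if n_blocks == 1:
        return np.array([budget])
    cuts = np.sort(rng.uniform(0.0, budget, size=n_blocks - 1))
    bounds = np.round(np.concatenate(([0.0], cuts, [budget]))).astype(np.int64)
    lengths = np.diff(bounds)
    return lengths[lengths > 0]


def plan_degradation(
    contig_lengths: Mapping[str, int] | Sequence[int],
    target_completeness: float,
    n_blocks: int = 10,
    seed: int = 0,
    max_retries: int = 100,
) -> DegradationPlan:
    """Choose disjoint removal intervals hitting a target completeness.

    ``contig_lengths`` may be a mapping id -> length or a plain sequence of
    lengths (ids are then ``contig_1``, ``contig_2``, ...). A block that
    cannot be placed after ``max_retries`` uniform redraws is shrunk to the
    largest remaining free gap; an empty gap is an error suggesting fewer
    or smaller blocks.
    """
    if not 0.0 < target_completeness <= 1.0:
        raise ValueError("target_completeness must lie in (0, 1]")
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1")
    if not isinstance(contig_lengths, Mapping):
        contig_lengths = {
            f"contig_{i + 1}": int(length) for i, length in enumerate(contig_lengths)
        }
    lengths = {str(k): int(v) for k, v in contig_lengths.items()}
    if any(v <= 0 for v in lengths.values()):
        raise ValueError("contig lengths must be positive")
    total = sum(lengths.values())
    if total == 0:
        raise ValueError("assembly has zero total length")
    budget = int(round((1.0 - target_completeness) * total))
    if budget >= total:
        raise ValueError(
            f"removal budget {budget} >= total length {total}; "
            "target completeness too low"
        )
    plan = DegradationPlan(
        target_completeness=target_completeness,
        intervals=[],
        contig_lengths=lengths,
        seed=seed,
    )
    if budget == 0:
        return plan
    rng = np.random.default_rng(seed)
    ids = list(lengths)
    weights = np.array([lengths[c] for c in ids], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in ids}
    shrunk = 0
    for block_len in sorted(_split_budget(budget, n_blocks, rng), reverse=True):
        block_len = int(block_len)
        placed = False
        for _ in range(max_retries):
            contig = ids[int(rng.choice(len(ids), p=weights))]
            clen = lengths[contig]
            if block_len > clen:
                continue
            start = int(rng.integers(0, clen - block_len + 1))
            end = start + block_len
            if any(start < e and s < end for s, e in occupied[contig]):
                continue
            occupied[contig].append((start, end))
            plan.intervals.append((contig, start, end))
            placed = True
            break
        if not placed:
            gap = _largest_free_gap(lengths, occupied)
            if gap is None:
                raise ValueError(
                    "could not place removal block: no free gap left; "
                    "try fewer or smaller blocks"
                )
            contig, g_start, g_end = gap
            end = g_start + min(block_len, g_end - g_start)
            occupied[contig].append((g_start, end))
            plan.intervals.append((contig, g_start, end))
            shrunk += 1
    plan.shrunk_blocks = shrunk
    plan.intervals.sort()
    return DegradationPlan(
        target_completeness=target_completeness,
        intervals=plan.intervals,
        contig_lengths=lengths,
        seed=seed,
        shrunk_blocks=shrunk,
    )


def _largest_free_gap(
    lengths: Mapping[str, int], occupied: Mapping[str, list[tuple[int, int]]]
) -> tuple[str, int, int] | None:
    best: tuple[str, int, int] | None = None
    for contig, clen in lengths.items():
        edges = sorted(occupied[contig])
        cursor = 0
        for s, e in edges + [(clen, clen)]:
            if s - cursor > 0 and (best is None or s - cursor > best[2] - best[1]):
                best = (contig, cursor, s)
            cursor = max(cursor, e)
    return best


def _degrade_records(
    records: list[SeqRecord],
    plan: DegradationPlan,
    mode: Literal["excise", "split"],
) -> list[SeqRecord]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in plan.intervals:
        by_contig.setdefault(contig, []).append((start, end))
    seen = {rec.id: len(rec.seq) for rec in records}
    for contig in by_contig:
        if contig not in seen:
            raise ValueError(f"plan refers to contig {contig!r} absent from FASTA")
        if plan.contig_lengths[contig] != seen[contig]:
            raise ValueError(
                f"contig {contig!r} length mismatch: plan has "
                f"{plan.contig_lengths[contig]}, FASTA has {seen[contig]}"
            )
    out: list[SeqRecord] = []
    for rec in records:
        ivals = sorted(by_contig.get(rec.id, []))
        if not ivals:
            out.append(rec)
            continue
        pieces: list[str] = []
        cursor = 0
        seq = str(rec.seq)
        for start, end in ivals:
            if start > cursor:
                pieces.append(seq[cursor:start])
            cursor = end
        if cursor < len(seq):
            pieces.append(seq[cursor:])
        pieces = [p for p in pieces if p]
        if mode == "excise":
            joined = "".join(pieces)
            if joined:
                out.append(SeqRecord(Seq(joined), id=rec.id, description=""))
        elif mode == "split":
            for k, piece in enumerate(pieces, start=1):
                out.append(
                    SeqRecord(Seq(piece), id=f"{rec.id}_part{k}", description="")
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def apply_degradation(
    fasta_in: str | Path,
    plan: DegradationPlan,
    fasta_out: str | Path,
    mode: Literal["excise", "split"] = "split",
) -> int:
    """Apply a degradation plan to an assembly FASTA.

    ``excise`` deletes each interval and joins the flanks within one record;
    ``split`` cuts the contig into separate records at removed intervals
    (suffixes ``_part1``, ``_part2``, ... keep ids unique), which mimics
    real MAG fragmentation. Every output sequence is a verbatim substring
    of an input sequence. Returns the total output length in bp.
    """
    records = list(SeqIO.parse(str(fasta_in), "fasta"))
    if not records:
        raise ValueError(f"{fasta_in}: no FASTA records")
    out = _degrade_records(records, plan, mode)
    SeqIO.write(out, str(fasta_out), "fasta")
    return sum(len(rec.seq) for rec in out)


def write_plan(plan: DegradationPlan, path: str | Path) -> None:
    """Write removal intervals as TSV (contig, start, end; 0-based half-open)."""
    with Path(path).open("w") as handle:
        handle.write("contig\tstart\tend\n")
        for contig, start, end in plan.intervals:
            handle.write(f"{contig}\t{start}\t{end}\n")


def degrade_collection(
    fasta_dir: str | Path,
    completeness_source,
    out_dir: str | Path,
    n_blocks: int = 10,
    seed: int = 0,
    mode: Literal["excise", "split"] = "split",
) -> CompletenessTable:
    """Degrade every assembly in a directory toward drawn completeness targets.

    One target completeness is drawn per assembly from
    ``completeness_source`` (see :func:`pancore.pansim.draw_completeness`;
    an empirical list whose length equals the number of assemblies is used
    in file order). Degraded FASTAs are written alongside a realized-
    completeness TSV in the dialect :func:`pancore.matrix_io.read_completeness`
    accepts. Returns the realized completeness table.
    """
    fasta_dir = Path(fasta_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(
        p for p in fasta_dir.iterdir() if p.suffix.lower() in FASTA_SUFFIXES
    )
    if not files:
        raise ValueError(f"{fasta_dir}: no FASTA files ({'/'.join(FASTA_SUFFIXES)})")
    rng = np.random.default_rng(seed)
    targets = draw_completeness(completeness_source, len(files), rng)
    genome_ids: list[str] = []
    realized: list[float] = []
    for path, target in zip(files, targets):
        try:
            records = list(SeqIO.parse(str(path), "fasta"))
        except Exception as exc:  # pragma: no cover - biopython raises ValueError
            raise ValueError(f"unreadable FASTA {path}: {exc}") from exc
        if not records:
            raise ValueError(f"unreadable FASTA {path}: no records")
        lengths = {rec.id: len(rec.seq) for rec in records}
        plan = plan_degradation(
            lengths,
            float(target),
            n_blocks=n_blocks,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out_fasta = out_dir / path.name
        SeqIO.write(_degrade_records(records, plan, mode), str(out_fasta), "fasta")
        if plan.shrunk_blocks:
            warnings.warn(
                f"{path.name}: {plan.shrunk_blocks} block(s) shrunk to fit; "
                "realized completeness may exceed target",
                stacklevel=2,
            )
        genome_ids.append(path.stem)
        realized.append(plan.realized_completeness)
    table = CompletenessTable(genome_ids, np.array(realized))
    write_completeness(table, out_dir / "completeness.tsv")
    return table
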