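"""Telomeric hairpin constructs for strand-separation assays.

The long construct has a 169-bp stem whose G-rich strand reads, in the
unzipping direction (fork end first):

    18 bp random fork sequence
    10 x TTAGGG
    TGG spacer            (first base at stem position 79)
    10 x TTAGGG
    CGTC spacer           (first base at stem position 142)
    3 x TTAGGG
    6 bp loop-side filler

closed by a 4-nt thymine loop.  The two non-telomeric spacers break the
repeat register and are not TRF1 binding sites.  The short construct
keeps 13 repeats (10 + TGG + 3) on the same fork scaffold.

Stem positions are 1-based and counted from the fork end in the
unzipping direction, so "TGG at the 79th bp" means the spacer's first
base is the 79th base pair the fork opens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["HairpinConstruct", "build_hairpin", "REPEAT_UNIT"]

REPEAT_UNIT = "TTAGGG"
_VALID = set("ACGT")

# Fixed 18-bp non-telomeric fork sequence (synthetic; any non-repeat
# sequence breaks the telomeric register equally well).
DEFAULT_FORK_SEQUENCE = "GCATCTAGACGATCCGTA"
DEFAULT_LOOP_FILLER = "GATCCG"
DEFAULT_LOOP = "TTTT"


@dataclass(frozen=True)
class HairpinConstruct:
    """Hairpin stem layout with spacer coordinates in unzipping order."""

    stem_sequence: str          # G-rich strand, fork end first
    spacer_positions: tuple[int, ...]  # 1-based first-base positions
    spacer_lengths: tuple[int, ...]
    loop: str = DEFAULT_LOOP
    handle_bp: int = 700
    name: str = "hairpin"

    @property
    def stem_length(self) -> int:
        return len(self.stem_sequence)

    def spacer_windows(self) -> list[tuple[int, int]]:
        """Inclusive (start, end) stem positions occupied by each spacer."""
        return [(p, p + n - 1)
                for p, n in zip(self.spacer_positions, self.spacer_lengths)]

    def dimer_sites(self) -> list[int]:
        """End positions (1-based, inclusive) of every 12-bp tandem-repeat
        footprint (two adjacent TTAGGG units) that a TRF1 dimer can occupy.

        A footprint is valid when bases ``end-11 .. end`` are two intact
        repeat units, which excludes anything straddling a spacer.
        """
        unit2 = REPEAT_UNIT * 2
        seq = self.stem_sequence
        return [i + 12 for i in range(len(seq) - 11) if seq[i:i + 12] == unit2]


def build_hairpin(long: bool = True,
                  fork_sequence: str = DEFAULT_FORK_SEQUENCE,
                  repeat_counts: tuple[int, ...] | None = None,
                  spacers: tuple[str, ...] | None = None,
                  loop_filler: str = DEFAULT_LOOP_FILLER,
                  loop: str = DEFAULT_LOOP,
                  handle_bp: int = 700) -> HairpinConstruct:
    """Assemble a hairpin construct from its blocks.

    Parameters
    ----------
    long : bool
        True for the 23-repeat (169 bp) construct, False for the
        13-repeat short one.  ``repeat_counts``/``spacers`` override the
        block structure: blocks alternate repeats, spacer, repeats, ...
    """
    if repeat_counts is None:
        repeat_counts = (10, 10, 3) if long else (10, 3)
    if spacers is None:
        spacers = ("TGG", "CGTC")[: len(repeat_counts) - 1]
    if len(spacers) != len(repeat_counts) - 1:
        raise ValueError("need one spacer between each pair of repeat blocks")
    if any(c <= 0 for c in repeat_counts):
        raise ValueError("repeat counts must be positive")
    for block in (fork_sequence, loop_filler, loop, *spacers):
        if set(block) - _VALID:
            raise ValueError(f"non-ACGT characters in block {block!r}")

    parts = [fork_sequence]
    positions: list[int] = []
    lengths: list[int] = []
    pos = len(fork_sequence)
    for i, count in enumerate(repeat_counts):
        parts.append(REPEAT_UNIT * count)
        pos += 6 * count
        if i < len(spacers):
            positions.append(pos + 1)  # 1-based first base of the spacer
            lengths.append(len(spacers[i]))
            parts.append(spacers[i])
            pos += len(spacers[i])
    parts.append(loop_filler)
    stem = "".join(parts)
    return HairpinConstruct(
        stem_sequence=stem,
        spacer_positions=tuple(positions),
        spacer_lengths=tuple(lengths),
        loop=loop,
        handle_bp=handle_bp,
        name="telomeric_hairpin_long" if long else "telomeric_hairpin_short",
    )


def write_fasta(construct: HairpinConstruct, path) -> None:
    """Write the stem (G-rich strand, fork end first) as FASTA."""
    with open(path, "w") as fh:
        fh.write(f">{construct.name} stem={construct.stem_length}bp "
                 f"spacers={','.join(map(str, construct.spacer_positions))}\n")
        seq = construct.stem_sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")
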