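"""Readers and writers for every external format the pipeline touches.

Formats:

* FASTA for protein sequences (via Biopython).
* PSI-MITAB 2.7 for interaction records, IntAct-compatible: 42 tab-separated
  columns, ``-`` for empty fields, with phospho-dependence and the kinase
  profile carried in the interaction-annotation column as
  ``comment:"py-dependent"`` / ``comment:"py-independent"`` and
  ``comment:"kinase-profile:FYN,SYK"``. A plain TSV dialect (columns
  ``bait_id  prey_id  dependence  kinase_profile  source``) is also supported
  and auto-detected on read.
* TSV tables for motifs (``reader_id  name  pattern``), phospho-sites
  (``protein_id  position``), pooled-screen observations, retest matrices
  (long format, one condition per row), kinase-plate profiles and co-IP
  triplicates.
* GMT for annotation gene sets.

Motif pattern grammar: a pattern is a string over residue letters, ``x``
(wildcard) and bracketed residue sets such as ``[ST]``, with a single bare
``Y`` marking the phospho-tyrosine anchor. ``YExM`` compiles to
``{+1: {E}, +3: {M}}``; ``NPxY`` to ``{-3: {N}, -2: {P}}``. A constrained
(non-anchor) tyrosine is written ``[Y]``.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .types import (
    AMINO_ACIDS,
    DEPENDENCE_LABELS,
    CoIPMeasurement,
    InteractionRecord,
    KinaseProfileVector,
    LinearMotif,
    ProteinRecord,
    RetestMatrix,
    ScreenObservation,
)

MITAB_N_COLUMNS = 42
_MITAB_HEADER = (
    "#ID(s) interactor A\tID(s) interactor B\t"
    + "\t".join(f"column {i}" for i in range(3, MITAB_N_COLUMNS + 1))
)
_ANNOT_COL = 27  # 0-based index of "Annotation(s) interaction" in MITAB 2.7


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read sequences from FASTA into :class:`ProteinRecord` (sequence only).

    Raises ``ValueError`` on duplicate identifiers or on non-amino-acid
    characters, naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Motif patterns
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\[[A-Z]+\]|[A-WYZ]|x")


def compile_motif_pattern(pattern: str) -> dict[int, frozenset[str]]:
    """Compile a pattern string to offset constraints relative to the pY anchor."""
    tokens = _TOKEN_RE.findall(pattern)
    if "".join(tokens) != pattern:
        raise ValueError(f"pattern {pattern!r}: unparseable characters")
    anchors = [i for i, t in enumerate(tokens) if t == "Y"]
    if len(anchors) != 1:
        raise ValueError(
            f"pattern {pattern!r}: exactly one bare 'Y' anchor required "
            f"(found {len(anchors)}); write a constrained tyrosine as [Y]"
        )
    anchor = anchors[0]
    constraints: dict[int, frozenset[str]] = {}
    for i, tok in enumerate(tokens):
        if i == anchor or tok == "x":
            continue
        residues = frozenset(tok.strip("[]"))
        if not residues <= AMINO_ACIDS:
            raise ValueError(f"pattern {pattern!r}: invalid residues in {tok!r}")
        constraints[i - anchor] = residues
    if not constraints:
        raise ValueError(f"pattern {pattern!r}: no constrained positions")
    return constraints


def format_motif_pattern(constraints: dict[int, frozenset[str]]) -> str:
    """Inverse of :func:`compile_motif_pattern` (canonical form)."""
    lo = min(min(constraints), 0)
    hi = max(max(constraints), 0)
    out = []
    for o in range(lo, hi + 1):
        if o == 0:
            out.append("Y")
        elif o in constraints:
            residues = "".join(sorted(constraints[o]))
            out.append(residues if len(residues) == 1 and residues != "Y" else f"[{residues}]")
        else:
            out.append("x")
    return "".join(out)


def read_motif_table(path: str | Path) -> list[LinearMotif]:
    """Read a TSV with columns ``reader_id``, ``name``, ``pattern``."""
    motifs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            motifs.append(
                LinearMotif(
                    reader_id=row["reader_id"],
                    name=row["name"],
                    constraints=compile_motif_pattern(row["pattern"]),
                )
            )
    return motifs


def write_motif_table(motifs: Iterable[LinearMotif], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["reader_id", "name", "pattern"])
        for m in motifs:
            w.writerow([m.reader_id, m.name, format_motif_pattern(m.constraints)])


# ---------------------------------------------------------------------------
# Interactions: PSI-MITAB 2.7 and plain TSV
# ---------------------------------------------------------------------------

def write_mitab(interactions: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write interactions as PSI-MITAB 2.7 (42 columns, '-' for empty)."""
    with open(path, "w") as fh:
        fh.write(_MITAB_HEADER + "\n")
        for rec in interactions:
            cols = ["-"] * MITAB_N_COLUMNS
            cols[0] = f"entrez gene/locuslink:{rec.bait_id}"
            cols[1] = f"entrez gene/locuslink:{rec.prey_id}"
            annots = [f'comment:"py-{rec.dependence}"', f'comment:"source:{rec.source}"']
            if rec.kinase_profile:
                annots.append(
                    'comment:"kinase-profile:' + ",".join(sorted(rec.kinase_profile)) + '"'
                )
            cols[_ANNOT_COL] = "|".join(annots)
            fh.write("\t".join(cols) + "\n")


def _parse_mitab_line(cols: list[str], lineno: int) -> InteractionRecord:
    def strip_prefix(value: str) -> str:
        return value.split(":", 1)[1] if ":" in value else value

    bait = strip_prefix(cols[0])
    prey = strip_prefix(cols[1])
    dependence = None
    source = "screen"
    profile: frozenset[str] = frozenset()
    for annot in cols[_ANNOT_COL].split("|"):
        m = re.fullmatch(r'comment:"(.*)"', annot)
        if not m:
            continue
        body = m.group(1)
        if body.startswith("py-"):
            dependence = body[3:]
        elif body.startswith("source:"):
            source = body[len("source:"):]
        elif body.startswith("kinase-profile:"):
            profile = frozenset(body[len("kinase-profile:"):].split(","))
    if dependence not in DEPENDENCE_LABELS:
        raise ValueError(f"line {lineno}: missing or unknown dependence annotation")
    return InteractionRecord(bait, prey, dependence, profile, source)


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read interactions from PSI-MITAB 2.7 or the plain TSV dialect.

    The format is auto-detected from the header / column count. Malformed
    lines are reported with their line number.
    """
    records: list[InteractionRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None and cols[0] == "bait_id":
                header = cols
                continue
            if len(cols) == MITAB_N_COLUMNS:
                records.append(_parse_mitab_line(cols, lineno))
            elif header is not None or 3 <= len(cols) <= 6:
                row = dict(zip(header or ["bait_id", "prey_id", "dependence",
                                          "kinase_profile", "source",
                                          "bait_kinase_caveat"], cols))
                dependence = row.get("dependence", "")
                if dependence not in DEPENDENCE_LABELS:
                    raise ValueError(
                        f"line {lineno}: unknown dependence token {dependence!r}"
                    )
                profile_field = row.get("kinase_profile", "-")
                profile = (
                    frozenset() if profile_field in ("-", "")
                    else frozenset(profile_field.split(","))
                )
                records.append(
                    InteractionRecord(
                        row["bait_id"],
                        row["prey_id"],
                        dependence,
                        profile,
                        row.get("source", "screen") or "screen",
                        row.get("bait_kinase_caveat", "0") in ("1", "true", "True"),
                    )
                )
            else:
                raise ValueError(
                    f"line {lineno}: expected {MITAB_N_COLUMNS} (MITAB) or TSV "
                    f"columns, got {len(cols)}"
                )
    return records


def write_interaction_tsv(interactions: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write the plain TSV dialect of the interaction table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["bait_id", "prey_id", "dependence", "kinase_profile", "source",
                    "bait_kinase_caveat"])
        for rec in interactions:
            w.writerow([
                rec.bait_id,
                rec.prey_id,
                rec.dependence,
                ",".join(sorted(rec.kinase_profile)) or "-",
                rec.source,
                int(rec.bait_kinase_caveat),
            ])


# ---------------------------------------------------------------------------
# Simple TSV tables
# ---------------------------------------------------------------------------

def read_phospho_sites(path: str | Path) -> dict[str, set[int]]:
    """Read a phospho-site table (columns ``protein_id``, ``position``, 1-based)."""
    sites: dict[str, set[int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sites.setdefault(row["protein_id"], set()).add(int(row["position"]))
    return sites


def write_phospho_sites(sites: dict[str, Iterable[int]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "position"])
        for pid in sorted(sites):
            for pos in sorted(sites[pid]):
                w.writerow([pid, pos])


def read_screen_observations(path: str | Path) -> list[ScreenObservation]:
    """Read pooled-screen growth (columns ``bait_id``, ``prey_id``, ``replica_growth``
    with growth encoded as a comma-separated 0/1 string, e.g. ``1,1,0,0``)."""
    obs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            growth = tuple(tok == "1" for tok in row["replica_growth"].split(","))
            obs.append(ScreenObservation(row["bait_id"], row["prey_id"], growth))
    return obs


def write_screen_observations(obs: Iterable[ScreenObservation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["bait_id", "prey_id", "replica_growth"])
        for o in obs:
            w.writerow([o.bait_id, o.prey_id, ",".join(str(int(g)) for g in o.replica_growth)])


def read_retest_matrices(path: str | Path) -> list[RetestMatrix]:
    """Read retest growth in long format: one row per (pair, condition).

    Columns: ``bait_id``, ``prey_id``, ``condition``, ``is_control`` (0/1),
    ``rep1``, ``rep2``.
    """
    acc: dict[tuple[str, str], tuple[dict, set]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["bait_id"], row["prey_id"])
            conditions, controls = acc.setdefault(key, ({}, set()))
            conditions[row["condition"]] = (row["rep1"] == "1", row["rep2"] == "1")
            if row["is_control"] == "1":
                controls.add(row["condition"])
    return [
        RetestMatrix(bait, prey, conditions, frozenset(controls))
        for (bait, prey), (conditions, controls) in acc.items()
    ]


def write_retest_matrices(matrices: Iterable[RetestMatrix], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["bait_id", "prey_id", "condition", "is_control", "rep1", "rep2"])
        for m in matrices:
            for cond in sorted(m.conditions):
                a, b = m.conditions[cond]
                w.writerow([m.bait_id, m.prey_id, cond,
                            int(cond in m.controls), int(a), int(b)])


def read_kinase_profiles(path: str | Path) -> list[KinaseProfileVector]:
    """Read kinase-plate profiles (columns ``interaction_id``, ``spots``;
    spots pipe-separated, ``-`` for empty)."""
    profiles = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            spots = row["spots"]
            profiles.append(
                KinaseProfileVector(
                    row["interaction_id"],
                    frozenset() if spots in ("-", "") else frozenset(spots.split("|")),
                )
            )
    return profiles


def write_kinase_profiles(profiles: Iterable[KinaseProfileVector], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["interaction_id", "spots"])
        for p in profiles:
            w.writerow([p.interaction_id, "|".join(sorted(p.spots)) or "-"])


def read_coip_table(path: str | Path) -> list[CoIPMeasurement]:
    """Read co-IP triplicates (columns ``pair_id``, ``s1..s3``, ``b1..b3``, ``valid``)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                CoIPMeasurement(
                    row["pair_id"],
                    (float(row["s1"]), float(row["s2"]), float(row["s3"])),
                    (float(row["b1"]), float(row["b2"]), float(row["b3"])),
                    row.get("valid", "1") == "1",
                )
            )
    return out


def write_coip_table(measurements: Iterable[CoIPMeasurement], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pair_id", "s1", "s2", "s3", "b1", "b2", "b3", "valid"])
        for m in measurements:
            w.writerow([m.pair_id, *(f"{x:.6g}" for x in m.signal),
                        *(f"{x:.6g}" for x in m.background), int(m.valid)])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read annotation gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"line {lineno}: GMT rows need >= 3 columns")
            sets[cols[0]] = set(filter(None, cols[2:]))
    return sets


def write_gmt(sets: dict[str, Sequence[str] | set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "na", *sorted(sets[name])]) + "\n")
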