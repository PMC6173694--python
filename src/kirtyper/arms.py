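"""ARMS amplification prediction and the allele × reaction pattern matrix.

ARMS (amplification refractory mutation system) primers place their
3'-terminal base on a discriminating SNP: Taq polymerase lacks 3'→5'
proofreading, so a 3'-terminal mismatch blocks extension and the reaction
reports the targeted allele by presence or absence of a band.  This module
scans allele sequences for primer binding sites under a configurable
refractoriness policy, predicts amplicons for multiplex reactions, and
assembles the boolean allele × reaction expected-amplification matrix that
serves as the typing knowledge base.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .alleles import AlleleRecord

_IUPAC_SETS = {code: frozenset(vals) for code, vals in ambiguous_dna_values.items()}
_IUPAC_SETS["-"] = frozenset()
_IUPAC_SETS["."] = frozenset()


def _bases_match(primer_base: str, template_base: str) -> bool:
    # A primer base pairs if the template's IUPAC set shares a base with
    # the primer's set; N therefore matches everything.
    ps = _IUPAC_SETS.get(primer_base)
    ts = _IUPAC_SETS.get(template_base)
    if ps is None or ts is None:
        return False
    return bool(ps & ts)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Primer:
    """One PCR primer, written 5'→3'.

    ``target_position`` is the 1-based coordinate, on the named reference
    accession, of the template base paired with the primer's 3'-terminal
    base (``None`` for non-discriminating primers).  ``position_offset``
    records any discrepancy between that printed coordinate and the
    coordinate recovered from the printed amplicon size; it is never
    silently folded into ``target_position``.
    """

    name: str
    sequence: str
    role: str  # "forward" | "reverse"
    target_position: int | None = None
    reference_id: str | None = None
    position_offset: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer role must be forward/reverse, got {self.role!r}")
        if len(self.sequence) < 15:
            raise ValueError(f"primer {self.name}: sequence shorter than 15 nt")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class ReactionDef:
    """One multiplex reaction: primer set, expected product, control status."""

    reaction_id: str
    gene_panel: str
    forward_primers: list[Primer]
    reverse_primers: list[Primer]
    expected_amplicon_bp: int | None = None
    includes_control: bool = True

    def __post_init__(self) -> None:
        if not self.forward_primers or not self.reverse_primers:
            raise ValueError(f"{self.reaction_id}: needs >=1 forward and reverse primer")


@dataclass
class ArmsPolicy:
    """Refractoriness policy for ARMS binding-site evaluation.

    k_terminal
        Number of 3'-terminal bases that must match exactly (default 1:
        terminal discrimination is absolute).
    max_3prime_window_mismatches
        Mismatches tolerated in the 5 bases immediately 5' of the terminal
        block — ARMS primers often carry a deliberate destabilizing
        penultimate mismatch, which must not abolish the intended product.
    max_total_mismatches
        Mismatch budget over the whole primer footprint.
    """

    k_terminal: int = 1
    max_3prime_window_mismatches: int = 1
    max_total_mismatches: int = 3
    max_amplicon_len: int = 5000
    window_size: int = 5

    def __post_init__(self) -> None:
        if self.k_terminal < 1:
            raise ValueError("k_terminal must be >= 1")
        for name in ("max_3prime_window_mismatches", "max_total_mismatches",
                     "max_amplicon_len", "window_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "ArmsPolicy":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass(frozen=True)
class BindingSite:
    """A candidate primer binding site on one strand of a template.

    ``template_position`` is the 1-based template coordinate of the base
    paired with the primer's 3' terminus.  ``five_prime`` is the plus-strand
    coordinate paired with the primer's 5' end (used for product-length
    arithmetic).  ``start``/``end`` delimit the plus-strand footprint.
    """

    template_position: int
    strand: str  # "+" | "-"
    total_mismatches: int
    terminal_match: bool
    refractory: bool
    start: int
    end: int
    five_prime: int


def find_binding_sites(primer: Primer, template: str, policy: ArmsPolicy | None = None) -> list[BindingSite]:
    """Scan both strands of *template* for binding sites of *primer*.

    All sites with at most ``max_total_mismatches`` mismatches are reported;
    each is marked refractory if the 3'-terminal block mismatches or the
    3' window budget is exceeded.  A primer longer than the template yields
    an empty list.
    """
    if not template:
        raise ValueError("empty template")
    if policy is None:
        policy = ArmsPolicy()
    template = template.upper()
    m = len(primer.sequence)
    L = len(template)
    if m > L:
        return []
    sites: list[BindingSite] = []
    k = policy.k_terminal
    w = policy.window_size
    for strand in ("+", "-"):
        # On the minus strand the primer binds the reverse complement, i.e.
        # revcomp(primer) appears on the plus strand with the primer's
        # 3' terminus paired to the leftmost footprint base.
        probe = primer.sequence if strand == "+" else revcomp(primer.sequence)
        for i in range(L - m + 1):
            total = 0
            terminal_mis = 0
            window_mis = 0
            ok = True
            # scan from the 3'-proximal end first for early exit
            for j3 in range(m):
                j = m - 1 - j3 if strand == "+" else j3
                if not _bases_match(probe[j], template[i + j]):
                    total += 1
                    if j3 < k:
                        terminal_mis += 1
                    elif j3 < k + w:
                        window_mis += 1
                    if total > policy.max_total_mismatches:
                        ok = False
                        break
            if not ok:
                continue
            terminal_match = terminal_mis == 0
            refractory = (not terminal_match) or window_mis > policy.max_3prime_window_mismatches
            if strand == "+":
                tpos, five = i + m, i + 1
            else:
                tpos, five = i + 1, i + m
            sites.append(
                BindingSite(
                    template_position=tpos,
                    strand=strand,
                    total_mismatches=total,
                    terminal_match=terminal_match,
                    refractory=refractory,
                    start=i + 1,
                    end=i + m,
                    five_prime=five,
                )
            )
    return sites


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product on one allele sequence (1-based inclusive)."""

    reaction_id: str
    allele_name: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def predict_amplicons(
    reaction: ReactionDef,
    allele: AlleleRecord,
    policy: ArmsPolicy | None = None,
) -> list[AmpliconPrediction]:
    """Predict all products of *reaction* on the genomic sequence of *allele*.

    A product forms for every pair of non-refractory (forward, reverse)
    sites on opposite strands in convergent orientation, counted from the
    upstream primer's 5' end through the downstream primer's 5' end
    inclusive — the standard PCR product definition, which includes both
    primer footprints.
    """
    if allele.genomic_sequence is None:
        raise ValueError(f"{allele.allele_name}: no genomic sequence")
    if policy is None:
        policy = ArmsPolicy()
    template = allele.genomic_sequence
    fsites = [
        s
        for p in reaction.forward_primers
        for s in find_binding_sites(p, template, policy)
        if not s.refractory
    ]
    rsites = [
        s
        for p in reaction.reverse_primers
        for s in find_binding_sites(p, template, policy)
        if not s.refractory
    ]
    seen = set()
    out = []
    for fs, rs in itertools.product(fsites, rsites):
        if fs.strand == rs.strand:
            continue  # divergent pairs cannot converge
        plus, minus = (fs, rs) if fs.strand == "+" else (rs, fs)
        if plus.start > minus.start or plus.end > minus.end:
            continue  # primers must point toward each other
        length = minus.five_prime - plus.five_prime + 1
        if length < 1 or length > policy.max_amplicon_len:
            continue
        key = (plus.five_prime, minus.five_prime)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            AmpliconPrediction(
                reaction_id=reaction.reaction_id,
                allele_name=allele.allele_name,
                start=plus.five_prime,
                end=minus.five_prime,
            )
        )
    return sorted(out, key=lambda a: (a.start, a.end))


# ---------------------------------------------------------------------------
# Pattern matrix
# ---------------------------------------------------------------------------


class PatternMatrix:
    """Boolean allele × reaction expected-amplification table.

    The typing knowledge base: cell (a, r) is True iff allele *a* is
    expected to yield a band in reaction *r*.  Each cell carries a
    provenance tag, ``"simulated"`` (computed by the ARMS engine) or
    ``"curated"`` (taken from a curated interpretation guide, which
    overrides simulation).
    """

    def __init__(self, df: pd.DataFrame, provenance: pd.DataFrame | None = None):
        self.df = df.astype(bool)
        if provenance is None:
            provenance = pd.DataFrame("simulated", index=df.index, columns=df.columns)
        if not provenance.index.equals(df.index) or not provenance.columns.equals(df.columns):
            raise ValueError("provenance frame does not match matrix shape")
        self.provenance = provenance

    @property
    def alleles(self) -> list[str]:
        return list(self.df.index)

    @property
    def reactions(self) -> list[str]:
        return list(self.df.columns)

    def row(self, allele: str) -> pd.Series:
        if allele not in self.df.index:
            raise KeyError(f"allele {allele} not in pattern matrix")
        return self.df.loc[allele]

    def resolvable_classes(self, reaction_subset: list[str] | None = None) -> list[list[str]]:
        """Partition alleles by equality of their rows restricted to
        *reaction_subset* (all reactions when ``None``; the empty subset
        puts every allele in one class).  Classes are ordered by their
        lexicographically smallest member."""
        if reaction_subset is None:
            reaction_subset = self.reactions
        unknown = [r for r in reaction_subset if r not in self.df.columns]
        if unknown:
            raise KeyError(f"unknown reaction ids: {unknown}")
        groups: dict[tuple, list[str]] = {}
        sub = self.df[list(reaction_subset)]
        for allele in self.df.index:
            key = tuple(bool(v) for v in sub.loc[allele])
            groups.setdefault(key, []).append(allele)
        classes = [sorted(members) for members in groups.values()]
        return sorted(classes, key=lambda c: c[0])

    def restrict(self, alleles: list[str]) -> "PatternMatrix":
        return PatternMatrix(self.df.loc[alleles], self.provenance.loc[alleles])

    def to_tsv(self, path, provenance_path=None) -> None:
        self.df.astype(int).to_csv(path, sep="\t")
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, provenance_path=None, provenance: str = "curated") -> "PatternMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(bool)
        if provenance_path is not None:
            prov = pd.read_csv(provenance_path, sep="\t", index_col=0)
        else:
            prov = pd.DataFrame(provenance, index=df.index, columns=df.columns)
        return cls(df, prov)


def build_pattern_matrix(
    reactions: list[ReactionDef],
    alleles: list[AlleleRecord],
    policy: ArmsPolicy | None = None,
    curated: PatternMatrix | None = None,
) -> PatternMatrix:
    """Assemble the allele × reaction matrix by in silico ARMS PCR.

    Cell (a, r) is True iff ``predict_amplicons`` is non-empty.  Alleles
    without genomic sequence must be fully covered by *curated* rows;
    curated cells override simulated ones, with provenance recorded per
    cell.
    """
    if policy is None:
        policy = ArmsPolicy()
    rids = [r.reaction_id for r in reactions]
    names = [a.allele_name for a in alleles]
    df = pd.DataFrame(False, index=names, columns=rids)
    prov = pd.DataFrame("simulated", index=names, columns=rids)
    missing = []
    for a in alleles:
        if a.genomic_sequence is None:
            if curated is None or a.allele_name not in curated.df.index:
                missing.append(a.allele_name)
                continue
        else:
            for r in reactions:
                df.loc[a.allele_name, r.reaction_id] = bool(
                    predict_amplicons(r, a, policy)
                )
    if missing:
        raise ValueError(f"alleles with neither sequence nor curated row: {missing}")
    if curated is not None:
        for a in curated.df.index.intersection(df.index):
            for r in curated.df.columns.intersection(df.columns):
                df.loc[a, r] = bool(curated.df.loc[a, r])
                prov.loc[a, r] = "curated"
    return PatternMatrix(df, prov)


def resolvable_classes(pm: PatternMatrix, reaction_subset: list[str] | None = None) -> list[list[str]]:
    """Module-level convenience wrapper around
    :meth:`PatternMatrix.resolvable_classes`."""
    return pm.resolvable_classes(reaction_subset)
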