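"""Readers and writers for the kit's tabular formats and packaged data.

Packaged data comprises the multiplex primer/reaction table of the typing
kit and a curated knowledge base (pattern matrices and subgroup
assignments).  The curated files carry ``synthetic`` in their names: they
are reconstructions built to satisfy the published panel structure
(subgroup counts, resolvable-class counts and class representatives), not
transcriptions of an external database.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .arms import PatternMatrix, Primer, ReactionDef
from .interpret import BandPattern
from .popgen import CohortGenotypes, Individual, Pedigree, SampleGenotype

#: Reactions without multiplexed control primers: a missing control band in
#: any other reaction voids that reaction, not these.
CONTROL_FREE_REACTIONS = frozenset(
    {"2DL1 Reaction 7 (3DP1)", "2DL1 Reaction 7 (3DP1V)", "2DL2 Reaction 4"}
)

#: The "main" reactions that define the phylogenetic subgroups of each gene
#: (the remaining reactions are supplemental, for within-group resolution).
MAIN_REACTIONS = {
    "KIR2DL1": [f"2DL1 Reaction {i}" for i in range(1, 7)],
    "KIR2DL2": [f"2DL2 Reaction {i}" for i in range(1, 5)],
    "KIR2DL3": [f"2DL3 Reaction {i}" for i in range(1, 6)],
}

_PATTERN_FILES = {
    "KIR2DL1": "kir2dl1_patterns_synthetic.tsv",
    "KIR2DL2": "kir2dl2_patterns_synthetic.tsv",
    "KIR2DL3": "kir2dl3_patterns_synthetic.tsv",
}


def _data_path(name: str):
    return resources.files("kirtyper.data").joinpath(name)


def read_primer_table(path=None) -> tuple[list[ReactionDef], tuple[Primer, Primer]]:
    """Parse a primer/reaction TSV (defaults to the packaged kit table).

    Returns the reaction definitions plus the DNA-quality control primer
    pair (813 bp product), which is multiplexed into every reaction except
    those in :data:`CONTROL_FREE_REACTIONS`.
    """
    if path is None:
        path = _data_path("table1_primers.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reactions: list[ReactionDef] = []
    control: list[Primer] = []
    for rid, block in df.groupby("reaction_id", sort=False):
        fwd, rev = [], []
        for _, row in block.iterrows():
            pos = None if row["target_position"] in ("NA", "", None) else int(row["target_position"])
            p = Primer(
                name=row["primer_name"],
                sequence=row["sequence"],
                role=row["role"],
                target_position=pos,
                reference_id=None if row["reference_id"] in ("NA", "", None) else row["reference_id"],
                position_offset=int(row.get("position_offset", 0) or 0),
            )
            (fwd if p.role == "forward" else rev).append(p)
        if rid == "Control":
            control = fwd + rev
            continue
        reactions.append(
            ReactionDef(
                reaction_id=rid,
                gene_panel=block["gene"].iloc[0],
                forward_primers=fwd,
                reverse_primers=rev,
                expected_amplicon_bp=int(block["amplicon_bp"].iloc[0]),
                includes_control=bool(int(block["includes_control"].iloc[0])),
            )
        )
    if len(control) != 2:
        raise ValueError("primer table must contain exactly one control primer pair")
    return reactions, (control[0], control[1])


def load_curated_patterns(gene: str) -> PatternMatrix:
    """Packaged curated pattern matrix for one gene panel."""
    if gene not in _PATTERN_FILES:
        raise KeyError(f"no curated panel for {gene}")
    with resources.as_file(_data_path(_PATTERN_FILES[gene])) as p:
        return PatternMatrix.from_tsv(p, provenance="curated")


def load_curated_kb() -> PatternMatrix:
    """Combined curated knowledge base over all three gene panels.

    Alleles of one gene are negative for the other genes' reactions
    (primer specificity across genes is a design property of the kit), so
    the combined matrix is block-structured.
    """
    parts = [load_curated_patterns(g) for g in ("KIR2DL1", "KIR2DL2", "KIR2DL3")]
    alleles = [a for pm in parts for a in pm.alleles]
    reactions = [r for pm in parts for r in pm.reactions]
    df = pd.DataFrame(False, index=alleles, columns=reactions)
    for pm in parts:
        df.loc[pm.alleles, pm.reactions] = pm.df.values
    prov = pd.DataFrame("curated", index=alleles, columns=reactions)
    return PatternMatrix(df, prov)


def load_curated_groups() -> pd.DataFrame:
    """Packaged allele → subgroup table (columns: allele, gene, group, tested)."""
    with resources.as_file(_data_path("kir2dl_groups_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def write_groups_tsv(assignment: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["allele", "group"]
    ).to_csv(path, sep="\t", index=False)


def read_band_patterns(path, control_free=CONTROL_FREE_REACTIONS) -> list[BandPattern]:
    """Read observed band patterns (long TSV: sample, reaction, band, control)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for sid, block in df.groupby("sample", sort=False):
        bands = {}
        controls = {}
        for _, row in block.iterrows():
            rid = row["reaction"]
            bands[rid] = bool(int(row["band"]))
            if "control" in row and str(row["control"]) not in ("", "nan", "NA"):
                controls[rid] = bool(int(row["control"]))
        out.append(
            BandPattern(
                sample_id=sid, bands=bands, controls=controls,
                control_free=frozenset(control_free),
            )
        )
    return out


def write_band_patterns(patterns: list[BandPattern], path) -> None:
    rows = []
    for p in patterns:
        for rid, v in p.bands.items():
            rows.append(
                {
                    "sample": p.sample_id,
                    "reaction": rid,
                    "band": int(v),
                    "control": "" if rid in p.control_free else int(p.controls.get(rid, True)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigrees(path) -> list[Pedigree]:
    """PED-like TSV: family, individual, father, mother + genotype columns.

    Empty father/mother fields mark founders.  Genotype columns follow the
    cohort format (kir2dl1_alleles, kir2dl23_alleles, kir2ds2)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    peds = []
    for fam, block in df.groupby("family", sort=False):
        individuals = []
        for _, row in block.iterrows():
            geno = None
            if row.get("kir2dl23_alleles", ""):
                geno = SampleGenotype(
                    sample_id=row["individual"],
                    dl1=tuple(x for x in row.get("kir2dl1_alleles", "").split(",") if x),
                    dl23=tuple(x for x in row["kir2dl23_alleles"].split(",") if x),  # type: ignore[arg-type]
                    ds2=bool(int(row.get("kir2ds2", "0") or 0)),
                )
            individuals.append(
                Individual(
                    individual_id=row["individual"],
                    father_id=row["father"] or None,
                    mother_id=row["mother"] or None,
                    genotype=geno,
                )
            )
        peds.append(Pedigree(fam, individuals))
    return peds


def write_pedigrees(peds: list[Pedigree], path) -> None:
    rows = []
    for ped in peds:
        for ind in ped.individuals.values():
            g = ind.genotype
            rows.append(
                {
                    "family": ped.family_id,
                    "individual": ind.individual_id,
                    "father": ind.father_id or "",
                    "mother": ind.mother_id or "",
                    "kir2dl1_alleles": ",".join(g.dl1) if g else "",
                    "kir2dl23_alleles": ",".join(g.dl23) if g else "",
                    "kir2ds2": int(g.ds2) if g else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> CohortGenotypes:
    return CohortGenotypes.from_tsv(path)
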