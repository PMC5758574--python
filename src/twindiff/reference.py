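"""Reference multi-study discordant-twin cohort design.

Seven published microarray studies of monozygotic twin pairs discordant for a
phenotype: ulcerative colitis (UC), chronic fatigue syndrome (CFS), physical
activity (PA), intelligence quotient (IQ), intermittent allergic rhinitis
assayed in vitro (IAR_invitro), major depressive disorder (MDD) and obesity
(OB). Five come from a public expression repository (GEO), one from a
controlled-access genotype/phenotype archive (dbGaP) and one from
ArrayExpress; together they span 10–44 pairs per study and five distinct
array platforms, and only the CFS, MDD and OB cohorts carry per-sample sex
labels. The synthetic-cohort generator uses this table as its default study
structure.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StudyDesign:
    phenotype: str
    n_pairs: int
    n_genes: int
    platform: str
    source: str  # repository the real study came from
    sex_labelled: bool


REFERENCE_STUDIES: tuple[StudyDesign, ...] = (
    StudyDesign("UC", 10, 22836, "GPL570", "GEO", False),
    StudyDesign("CFS", 44, 22836, "GPL570", "GEO", True),
    StudyDesign("PA", 10, 19429, "GPL6884", "GEO", False),
    StudyDesign("IQ", 17, 18638, "GPL6244", "GEO", False),
    StudyDesign("IAR_invitro", 11, 19580, "GPL6102", "GEO", False),
    StudyDesign("MDD", 28, 19284, "GPL13667", "dbGaP", True),
    StudyDesign("OB", 13, 22836, "GPL570", "ArrayExpress", True),
)

#: Unique genes measured across all seven platforms.
GENE_UNIVERSE_SIZE = 25154


def geo_pairs_total() -> int:
    """Total twin pairs contributed by the GEO studies."""
    return sum(s.n_pairs for s in REFERENCE_STUDIES if s.source == "GEO")


def pairs_range() -> tuple[int, int]:
    """(min, max) twin pairs over all reference studies."""
    counts = [s.n_pairs for s in REFERENCE_STUDIES]
    return min(counts), max(counts)
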