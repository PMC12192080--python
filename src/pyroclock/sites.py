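"""The five-gene / six-CpG pyrosequencing methylation panel.

The panel covers CpG sites in the promoter or gene-body regions of *KLF14*,
*FHL2*, *TRIM59*, *C1orf132* (MIR29B2CHG) and *ELOVL2* that are routinely
assayed by bisulfite pyrosequencing for blood-based age prediction.  All
sites gain methylation with age except the *C1orf132* site, which loses it.

Site keys combine gene symbol and the assay's CpG label (``GENE_LABEL``,
e.g. ``ELOVL2_C5``) because *ELOVL2* contributes two distinct CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CpGSite", "BUILTIN_SITES", "SITE_KEYS", "site_key"]


@dataclass(frozen=True)
class CpGSite:
    """A single assayed CpG position.

    Attributes
    ----------
    gene:
        HGNC gene symbol.
    site_label:
        Short CpG label used by the pyrosequencing assay (C1, C2, C5, C7).
    chromosome:
        Chromosome name (GRCh38).
    position:
        1-based GRCh38 coordinate of the cytosine.
    expected_direction:
        ``"hyper_with_age"`` if percent methylation increases with age,
        ``"hypo_with_age"`` if it decreases.
    """

    gene: str
    site_label: str
    chromosome: str
    position: int
    expected_direction: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")
        if self.expected_direction not in ("hyper_with_age", "hypo_with_age"):
            raise ValueError(f"unknown direction {self.expected_direction!r}")

    @property
    def key(self) -> str:
        return f"{self.gene}_{self.site_label}"


def site_key(gene: str, label: str) -> str:
    """Canonical ``GENE_LABEL`` key for a site."""
    return f"{gene}_{label}"


#: The six assayed CpG sites with their GRCh38 coordinates.
BUILTIN_SITES: dict[str, CpGSite] = {
    s.key: s
    for s in (
        CpGSite("KLF14", "C1", "chr7", 130734355, "hyper_with_age"),
        CpGSite("FHL2", "C2", "chr2", 105399288, "hyper_with_age"),
        CpGSite("TRIM59", "C7", "chr3", 160450199, "hyper_with_age"),
        CpGSite("C1orf132", "C1", "chr1", 207823681, "hypo_with_age"),
        CpGSite("ELOVL2", "C5", "chr6", 11044875, "hyper_with_age"),
        CpGSite("ELOVL2", "C7", "chr6", 11044867, "hyper_with_age"),
    )
}

#: Canonical column / reporting order of the panel.
SITE_KEYS: tuple[str, ...] = (
    "KLF14_C1",
    "FHL2_C2",
    "TRIM59_C7",
    "C1orf132_C1",
    "ELOVL2_C5",
    "ELOVL2_C7",
)
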