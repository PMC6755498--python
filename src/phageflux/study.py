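"""Metadata for the published *H. pylori* prophage genome panel.

One *H. acinonychis* prophage (Hac) plus 29 complete *H. pylori* prophage
genomes (>20 kb), each previously assigned to a phage population by
prophage sequence typing.  Two genomes are byte-identical copies of other
panel members after syntenic alignment (UK-EN32-U of UK-EN31-U,
Fr-MEG235-U of Fr-ANT170-U) and one carries a large inversion that cannot
be aligned without missing data (Pt-4481-G); excluding all three leaves 27
genomes for the painting analysis.

The panel here carries names, population assignments and genome lengths
only -- the sequences themselves live in public archives.
:func:`phageflux.synthdata.example_panel_alignment` builds a synthetic
alignment over this panel that reproduces the duplicate structure, for
exercising the exclusion filter end to end.
"""

from __future__ import annotations

# (genome, phage population, genome length bp)
GENOME_PANEL: list[tuple[str, str, int]] = [
    ("Hac", "na", 28420),
    ("KHP30", "hpEastAsia", 26215),
    ("KHP40", "hpEastAsia", 26449),
    ("1961P", "hpEastAsia", 26836),
    ("Fr-B58-M", "hpEastAsia", 22559),
    ("Pt-B92-G", "hpAfrica1", 30548),
    ("Pt-212-99R-U", "hpAfrica1", 23008),
    ("Pt-1293-U", "hpAfrica1", 30071),
    ("Pt-5771-G", "hpAfrica1", 29801),
    ("Pt-B89-G", "hpAfrica1", 27363),
    ("Pt-5322-G", "hpAfrica1", 28341),
    ("Fr-ANT170-U", "hpAfrica1", 31200),
    ("Fr-MEG235-U", "hpAfrica1", 31236),
    ("Pt-1846-U", "hpAfrica1", 27960),
    ("Pt-228_99G", "hpAfrica1", 30078),
    ("phiHP33", "hpAfrica1", 24645),
    ("Pt-4481-G", "hpAfrica1", 25388),
    ("UK-EN31-U", "hpNEurope", 30456),
    ("UK-EN32-U", "hpNEurope", 29882),
    ("De-M53-M", "hpNEurope", 28068),
    ("India7", "hpNEurope", 28310),
    ("Cuz20", "hpNEurope", 28587),
    ("Sw-A626-G", "hpNEurope", 30977),
    ("Sw-577-G", "hpNEurope", 26906),
    ("Fr-G12-G", "hpSWEurope", 28565),
    ("Pt-4472-G", "hpSWEurope", 27572),
    ("Fr-GC43-A", "hpSWEurope", 32975),
    ("Pt-1918-U", "hpSWEurope", 28670),
    ("Pt-4497-U", "hpSWEurope", 29393),
    ("Fr-B41-M", "hpSWEurope", 29388),
]

#: genomes identical, after alignment, to another panel member (copy, original)
IDENTICAL_PAIRS: list[tuple[str, str]] = [
    ("UK-EN32-U", "UK-EN31-U"),
    ("Fr-MEG235-U", "Fr-ANT170-U"),
]

#: genomes excluded by name (large inversion; painting allows no missing data)
INVERSION_EXCLUSIONS: list[str] = ["Pt-4481-G"]


def panel_ids() -> list[str]:
    return [g for g, _, _ in GENOME_PANEL]


def panel_labels() -> dict[str, str]:
    return {g: pop for g, pop, _ in GENOME_PANEL}
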