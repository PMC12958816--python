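"""Published C. elegans mtDNA base-substitution counts used as worked examples.

Counts are in the canonical class order of :data:`mitospectrum.spectrum.CLASSES`
(A/T->C/G, A/T->T/A, G/C->T/A, G/C->C/G, A/T->G/C, G/C->A/T).

Four small spectra are bundled:

``NATURAL_ISOLATES``
    2,376 polarized base substitutions from natural-isolate mitochondrial
    genomes (all sites), and the 900-SNP subset at four-fold degenerate
    sites (``NATURAL_ISOLATES_FOURFOLD``).
``DUPLEX_A`` / ``DUPLEX_B``
    Substitutions from two duplex-sequencing laboratory studies of
    spontaneous mtDNA mutation (253 and 760 SNPs); ``DUPLEX_A_FOURFOLD``
    is the four-fold subset of the former.
``MA_LINES``
    Nine substitutions from a long-term mutation-accumulation experiment.

These integer tables support the spectrum-contrast statistics (transition
vs transversion heterogeneity between studies, transition balance,
transversion-profile heterogeneity, A/T- vs G/C-increasing flux) without
any external data.
"""

from __future__ import annotations

from .spectrum import SpectrumTable

NATURAL_ISOLATES = (54, 226, 144, 9, 1062, 881)
NATURAL_ISOLATES_FOURFOLD = (39, 129, 48, 5, 387, 292)
DUPLEX_A = (2, 20, 79, 8, 50, 94)
DUPLEX_A_FOURFOLD = (1, 5, 4, 0, 10, 9)
DUPLEX_B = (22, 76, 300, 225, 44, 93)
MA_LINES = (0, 1, 3, 0, 0, 5)

#: Preferred-codon flux 2x2 from the natural-isolate synonymous variants:
#: rows = (rare, shared), columns = (from-preferred, to-preferred).
PREFERRED_FLUX_2X2 = ((357, 245), (364, 333))


def natural_isolates_table(stratum: str = "all") -> SpectrumTable:
    """SpectrumTable of the natural-isolate counts (``all`` or ``four``)."""
    if stratum == "all":
        return SpectrumTable.from_vector(NATURAL_ISOLATES, stratum="all")
    if stratum == "four":
        return SpectrumTable.from_vector(NATURAL_ISOLATES_FOURFOLD,
                                         stratum="four")
    raise ValueError(f"unknown stratum {stratum!r}")
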