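"""Bundled reference data.

``minimum_size_survey`` returns a published survey of per-criterion and
overall minimum sample sizes estimated for 19 empirical genotype datasets
(plants and animals, SSR and SNP markers).  It is the worked input for the
marker-type group comparison (Wilcoxon rank-sum on the overall minima) and
a fixture for the conservative overall rule (overall = max of the four
criterion minima).
"""

from __future__ import annotations

import pandas as pd

# category, species, common-allele minimum, allele-frequency minimum,
# FST minimum, He-difference minimum, overall minimum
_SURVEY_ROWS = [
    ("Plant SNP", "Acrocomia aculeata", 10, 5, 5, 10, 10),
    ("Plant SNP", "Casearia sylvestris", 10, 10, 10, 20, 20),
    ("Plant SNP", "Chloropyron maritimum", 5, 5, 10, 5, 10),
    ("Plant SNP", "Euterpe precatoria", 10, 10, 15, 10, 15),
    ("Plant SNP", "Manihot dulcis", 5, 10, 10, 15, 15),
    ("Plant SNP", "Manihot esculenta", 10, 10, 10, 20, 20),
    ("Plant SSR", "Bertholletia excelsa", 15, 10, 10, 15, 15),
    ("Plant SSR", "Caryocar villosum", 15, 5, 10, 15, 15),
    ("Plant SSR", "Casearia sylvestris", 40, 5, 10, 10, 40),
    ("Plant SSR", "Copaifera langsdorffii", 20, 5, 10, 10, 20),
    ("Plant SSR", "Erythrophleum suaveolens (pop 1)", 20, 10, 10, 25, 25),
    ("Plant SSR", "Erythrophleum suaveolens (pop 3)", 20, 5, 10, 15, 20),
    ("Plant SSR", "Eugenia dysenterica", 15, 10, 10, 10, 15),
    ("Plant SSR", "Metrosideros polymorpha", 25, 5, 10, 20, 25),
    ("Plant SSR", "Myroxylon peruiferum", 20, 15, 10, 25, 25),
    ("Plant SSR", "Shorea macrophylla", 20, 5, 10, 15, 20),
    ("Plant SSR", "Solanum lycocarpum", 15, 5, 10, 20, 20),
    ("Animal SNP", "Tetragonisca angustula", 5, 10, 10, 10, 10),
    ("Animal SSR", "Caiman crocodilus", 15, 10, 10, 15, 15),
]

CRITERION_COLUMNS = ["common_alleles", "allele_freq", "fst", "he_diff"]


def minimum_size_survey() -> pd.DataFrame:
    """Published minimum sample sizes for 19 empirical datasets.

    Columns: ``category`` (taxon + marker), ``marker`` (SSR/SNP),
    ``species``, the four per-criterion minima, and ``overall``.
    """
    df = pd.DataFrame(
        _SURVEY_ROWS,
        columns=["category", "species", *CRITERION_COLUMNS, "overall"],
    )
    df.insert(1, "marker", df["category"].str.split().str[-1])
    return df
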