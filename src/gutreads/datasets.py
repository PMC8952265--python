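"""Bundled benchmark observations from a gut-content field study.

Three small tables from a study of five epigeal arthropod predators (three
ants, an earwig, and a tiger beetle) sampled in Brazilian agricultural plots,
whose gut contents were analyzed in parallel by 16S metabarcoding and by
read-mapping (Lazaro), with melt-curve verification of every detection:

* ``mock_community()`` — read counts for a feeding trial in which *Harmonia
  axyridis* adults consumed seven known prey; the ground truth lets detection
  accuracy be computed without melt-curve confirmation.
* ``field_survey()`` — per-library counts of prey species initially detected
  by each method across the 27 field samples, the count detected by both,
  and the proportion of each library's detections verified by melt-curve
  analysis.
* ``species_confirmations()`` — the 30 candidate prey species detected at
  least once by either method, the method(s) that detected each, and whether
  any detection of the species was melt-curve confirmed.

These are observations, used as inputs to the evaluation module; nothing in
the package recomputes them.
"""

from __future__ import annotations

import pandas as pd

MOCK_PREY = [
    "Acyrthosiphon pisum", "Aphis craccivora", "Aphis glycines",
    "Aphis gossypii", "Myzus persicae", "Cycloneda munda",
    "Plutella xylostella",
]

MOCK_PREDATOR = "Harmonia axyridis"

# read counts 6 h after feeding; metabarcoding detected only the predator
_MOCK_ROWS = [
    # species, female_mb, female_lazaro, male_mb, male_lazaro, is_predator
    (MOCK_PREDATOR, 128773, 40498, 451571, 43452, True),
    ("Acyrthosiphon pisum", 0, 16, 0, 10, False),
    ("Aphis craccivora", 0, 26, 0, 4, False),
    ("Aphis glycines", 0, 2, 0, 0, False),
    ("Aphis gossypii", 0, 2, 0, 0, False),
    ("Myzus persicae", 0, 0, 0, 10, False),
    ("Cycloneda munda", 0, 6, 0, 0, False),
    ("Plutella xylostella", 0, 0, 0, 0, False),
]


def mock_community() -> pd.DataFrame:
    """Feeding-trial read counts (one row per species, predator flagged)."""
    return pd.DataFrame(
        _MOCK_ROWS,
        columns=["species", "female_metabarcoding", "female_lazaro",
                 "male_metabarcoding", "male_lazaro", "is_predator"],
    )


# per-library field results: predator, species detected by metabarcoding /
# Lazaro / both before verification, then the proportion of each method's
# detections verified by melt-curve analysis.
_FIELD_ROWS = [
    ("Pheidole flavens", 6, 6, 5, 0.40, 0.33, 0.40),
    ("Pheidole flavens", 5, 5, 4, 0.50, 0.50, 0.67),
    ("Pheidole flavens", 6, 6, 5, 0.20, 0.25, 0.25),
    ("Pheidole flavens", 6, 5, 5, 0.40, 0.40, 0.40),
    ("Pheidole flavens", 5, 6, 4, 0.33, 0.33, 0.33),
    ("Pheidole flavens", 5, 6, 5, 0.60, 0.50, 0.60),
    ("Pheidole flavens", 4, 6, 4, 0.33, 0.25, 0.33),
    ("Pheidole flavens", 4, 5, 4, 0.00, 0.00, 0.00),
    ("Pheidole flavens", 5, 7, 4, 0.67, 0.50, 0.67),
    ("Pheidole flavens", 4, 7, 4, 0.50, 0.33, 0.50),
    ("Pheidole flavens", 4, 6, 4, 0.33, 0.20, 0.33),
    ("Pheidole flavens", 5, 6, 3, 0.40, 0.40, 0.67),
    ("Dorymyrmex brunneus", 9, 6, 6, 0.29, 0.25, 0.33),
    ("Dorymyrmex brunneus", 10, 7, 5, 0.20, 0.20, 0.33),
    ("Dorymyrmex brunneus", 8, 4, 4, 0.20, 0.33, 0.33),
    ("Dorymyrmex brunneus", 6, 9, 5, 0.25, 0.33, 0.33),
    ("Dorymyrmex brunneus", 10, 5, 5, 0.25, 0.25, 0.25),
    ("Dorymyrmex brunneus", 11, 6, 5, 0.19, 0.33, 0.33),
    ("Dorymyrmex brunneus", 12, 8, 6, 0.33, 0.50, 0.67),
    ("Dorymyrmex brunneus", 10, 8, 5, 0.00, 0.00, 0.00),
    ("Dorymyrmex brunneus", 10, 6, 5, 0.43, 0.60, 0.75),
    ("Dorymyrmex brunneus", 8, 8, 5, 0.00, 0.00, 0.00),
    ("Dorymyrmex brunneus", 8, 6, 5, 0.40, 0.50, 0.67),
    ("Dorymyrmex brunneus", 13, 6, 5, 0.13, 0.33, 0.33),
    ("Solenopsis substituta", 12, 11, 8, 0.43, 0.50, 0.50),
    ("Tetracha sp.", 16, 15, 10, 0.45, 0.55, 0.50),
    ("Euborellia annulipes", 10, 7, 6, 0.33, 0.33, 0.33),
]


def field_survey() -> pd.DataFrame:
    """Per-library detection counts and melt-curve verification proportions
    for the 27 field samples."""
    return pd.DataFrame(
        _FIELD_ROWS,
        columns=["predator", "metabarcoding", "lazaro", "both",
                 "verified_metabarcoding", "verified_lazaro", "verified_both"],
    )


# the 30 candidate prey species: detecting method(s) and whether any
# detection was confirmed by melt-curve analysis in >= 1 library
_SPECIES_ROWS = [
    ("Phascolosoma esculenta", "metabarcoding", False),
    ("Anthonomus grandis", "both", True),
    ("Eriopis connexa", "both", False),
    ("Harmonia axyridis", "both", True),
    ("Selenophorus alternans", "both", False),
    ("Tetracha brasiliensis", "lazaro", False),
    ("Doru luteipes", "both", True),
    ("Euborellia annulipes", "both", True),
    ("Strongygaster triangulifera", "both", False),
    ("Chinavia impicticornes", "both", True),
    ("Euschistus heros", "both", True),
    ("Mahanarva spectabilis", "lazaro", True),
    ("Neomegalotomus parvus", "metabarcoding", False),
    ("Myzus persicae", "metabarcoding", False),
    ("Planicephalus flavicosta", "metabarcoding", False),
    ("Atta sextans", "both", False),
    ("Brachymyrmex patagonicus", "lazaro", False),
    ("Cardiocondyla obscurior", "both", True),
    ("Dorymyrmex brunneus", "both", True),
    ("Pheidole flavens", "both", True),
    ("Pheidole obscurithorax", "both", True),
    ("Pheidole oxyops", "both", True),
    ("Pheidole tristis", "both", True),
    ("Solenopsis richteri", "metabarcoding", False),
    ("Solenopsis substituta", "both", False),
    ("Syntermes spinosus", "metabarcoding", True),
    ("Chrysodeixis includens", "both", True),
    ("Glena unipennaria", "both", False),
    ("Spodoptera frugiperda", "metabarcoding", True),
    ("Gryllus argentinus", "metabarcoding", False),
]


def species_confirmations() -> pd.DataFrame:
    """The 30 candidate prey species with melt-curve confirmation flags."""
    return pd.DataFrame(
        _SPECIES_ROWS, columns=["species", "detection_method", "mca_confirmed"])
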