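"""Seed-reproducible synthetic 3D-MMS records and labeled fault injection.

The generator emulates the metadata a brain-microscopy repository
submission carries: a handful of contributors with ORCID/ROR
identifiers, government funders, a light-sheet or confocal instrument,
a multi-channel image stack with micron-scale step sizes, and a mouse
or human specimen.  Every generated record validates clean under the
repository profile; corrupted copies come with ground-truth labels so
validator coverage is testable with no external data.

One pseudo-random stream is derived per record from (master seed,
record index), so corpus membership is order-insensitive and corpora
are byte-identical across runs and platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .issues import VALIDATION_CODES
from .record import (
    ChannelEntry,
    ContributorEntry,
    FunderEntry,
    LandmarkEntry,
    MetadataRecord,
    PublicationEntry,
)
from .validation import iso7064_mod11_2_check_character

__all__ = [
    "GeneratorConfig",
    "FaultLabel",
    "generate_valid_record",
    "inject_errors",
    "generate_corpus",
    "random_orcid",
    "random_ror",
]

_FIRST = ("Ada", "Grace", "Alan", "Rosalind", "Barbara", "Santiago", "Rita",
          "David", "Mei", "Camillo", "June", "Torsten")
_LAST = ("Lovelace", "Hopper", "Turing", "Franklin", "McClintock", "Cajal",
         "Levi-Montalcini", "Hubel", "Golgi", "Wiesel", "Sakmann", "Moser")
_ORGS = ("Pittsburgh Supercomputing Center", "Allen Institute",
         "Cold Spring Harbor Laboratory", "Janelia Research Campus",
         "Max Planck Institute for Brain Research", "RIKEN Center for Brain Science")
_FUNDER_NAMES = ("National Institutes of Health", "National Science Foundation",
                 "European Research Council", "Wellcome Trust",
                 "Japan Agency for Medical Research and Development")
_WORDS = ("axonal", "projection", "whole-brain", "cleared", "cortical",
          "hippocampal", "vasculature", "neuronal", "morphology", "atlas",
          "registration", "tracing", "fluorescence", "volumetric", "imaging",
          "dataset", "acquisition", "reconstruction", "connectivity", "expression",
          "labeling", "stack", "mesoscale", "single-cell", "high-resolution")
_MICROSCOPES = (("light sheet", "Zeiss Lightsheet Z.1"),
                ("confocal", "Leica TCS SP8"),
                ("two photon", "Bruker Ultima 2Pplus"),
                ("light sheet", "LaVision UltraMicroscope II"))
_FLUOROPHORES = ("GFP", "tdTomato", "DAPI", "Alexa Fluor 647", "mCherry", "YFP")
_SPECIES = (("mouse", "10090"), ("human", "9606"), ("rat", "10116"),
            ("zebrafish", "7955"))
_ORGANS = ("brain", "spinal cord", "retina")
_LICENSES = (("CC BY 4.0", "CC-BY-4.0", "https://creativecommons.org/licenses/by/4.0/"),
             ("CC0 1.0", "CC0-1.0", "https://creativecommons.org/publicdomain/zero/1.0/"))
_MODALITIES = ("anatomy", "cell morphology", "connectivity", "population imaging")
_TECHNIQUES = ("anterograde tracing", "light sheet fluorescence microscopy",
               "serial two-photon tomography", "confocal microscopy")
_IMMERSIONS = ("Air", "Oil", "Water", "Glycerol")
_DETECTORS = ("sCMOS", "PMT", "EMCCD")
_ILLUMINATIONS = ("Epifluorescence", "Transmitted", "NonLinear")
_RELATIONS = ("IsSupplementTo", "IsCitedBy", "IsDescribedBy")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for record generation.

    Count ranges are inclusive ``(low, high)`` tuples; ``optional_fill_probability``
    is the chance each optional scalar is populated.
    """

    seed: int = 0
    n_contributors: tuple[int, int] = (1, 4)
    n_funders: tuple[int, int] = (1, 3)
    n_channels: tuple[int, int] = (1, 4)
    n_publications: tuple[int, int] = (0, 3)
    optional_fill_probability: float = 0.35
    funding_declared: bool = True
    abstract_min_words: int = 0  # >=100 mirrors the standard's guidance

    def __post_init__(self) -> None:
        for name in ("n_contributors", "n_funders", "n_channels", "n_publications"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range {lo, hi} is empty or negative")
        if not 0.0 <= self.optional_fill_probability <= 1.0:
            raise ValueError("optional_fill_probability must be in [0, 1]")


@dataclass(frozen=True)
class FaultLabel:
    """Ground truth for one injected fault."""

    path: str
    code: str
    description: str

    def __post_init__(self) -> None:
        if self.code not in VALIDATION_CODES:
            raise ValueError(f"unknown rule code {self.code!r}")


def _rng_for(seed: int, index: int) -> random.Random:
    # one independent stream per record, stable across platforms
    return random.Random((seed * 1_000_003 + index) % (2**31 - 1))


def random_orcid(rng: random.Random) -> str:
    body = "".join(str(rng.randrange(10)) for _ in range(15))
    full = body + iso7064_mod11_2_check_character(body)
    return "-".join(full[i:i + 4] for i in range(0, 16, 4))


def random_ror(rng: random.Random) -> str:
    alphabet = "0123456789abcdefghjkmnpqrstvwxyz"
    return "0" + "".join(rng.choice(alphabet) for _ in range(8))


def _words(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(n))


def _maybe(rng: random.Random, p: float, value):
    return value if rng.random() < p else None


def generate_valid_record(config: GeneratorConfig, index: int = 0) -> MetadataRecord:
    """Generate one record that validates clean under the ``bil`` profile.

    The same ``(config, index)`` always yields the identical record.
    """
    rng = _rng_for(config.seed, index)
    p = config.optional_fill_probability
    rec = MetadataRecord(funding_declared=config.funding_declared)

    n_contrib = rng.randint(*config.n_contributors)
    for i in range(n_contrib):
        personal = i == 0 or rng.random() < 0.7
        org = rng.choice(_ORGS)
        if personal:
            name = f"{rng.choice(_LAST)}, {rng.choice(_FIRST)}"
            ident, scheme = random_orcid(rng), "ORCID"
        else:
            name = org
            ident, scheme = random_ror(rng), "ROR"
        rec.contributors.append(ContributorEntry(
            contributor_name=name,
            creator=(i == 0) or rng.random() < 0.4,
            contributor_type="ProjectLeader" if i == 0 else rng.choice(
                ("Researcher", "DataCollector", "DataCurator", "ProjectMember")),
            name_type="Personal" if personal else "Organizational",
            name_identifier=ident,
            name_identifier_scheme=scheme,
            affiliation=org,
            affiliation_identifier=random_ror(rng),
            affiliation_identifier_scheme="ROR",
        ))

    if config.funding_declared:
        for i in range(rng.randint(*config.n_funders)):
            rec.funders.append(FunderEntry(
                funder_name=rng.choice(_FUNDER_NAMES),
                funding_reference_identifier=random_ror(rng),
                funding_reference_identifier_type="ROR",
                award_number=f"{rng.choice('RUF')}{rng.randrange(10, 99)}"
                             f"MH{rng.randrange(100000, 999999)}",
                award_title=_words(rng, 5).capitalize(),
            ))

    license_name, spdx, uri = rng.choice(_LICENSES)
    d = rec.dataset
    d.title = _words(rng, 6).capitalize()
    d.rights = license_name
    d.rights_uri = uri
    d.rights_identifier = spdx
    n_abstract = max(config.abstract_min_words, rng.randint(25, 60))
    d.abstract = (_words(rng, n_abstract) + ".").capitalize()
    d.general_modality = _maybe(rng, p, rng.choice(_MODALITIES))
    d.technique = _maybe(rng, p, rng.choice(_TECHNIQUES))
    d.methods = _maybe(rng, p, _words(rng, 12).capitalize() + ".")
    d.technical_info = _maybe(rng, p, _words(rng, 10).capitalize() + ".")
    d.keywords = _maybe(rng, p, "; ".join(sorted({rng.choice(_WORDS) for _ in range(3)})))
    d.dataset_date = _maybe(rng, p, f"202{rng.randrange(5)}-"
                                    f"{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}")
    d.related_project_name = _maybe(rng, p, "BICCN")

    img = rec.image
    img.x_axis, img.y_axis, img.z_axis = (
        "Left to right", "Superior to inferior", "Anterior to posterior")
    img.step_size_x = round(10 ** rng.uniform(-1, 1), 3)  # 0.1-10 um/px
    img.step_size_y = img.step_size_x
    img.step_size_z = round(10 ** rng.uniform(-0.5, 1.5), 3)
    for c in range(rng.randint(*config.n_channels)):
        img.channels.append(ChannelEntry(
            number=str(c),
            display_color=rng.choice(((255, 0, 0), (0, 255, 0), (0, 0, 255),
                                      (255, 255, 0), (255, 0, 255))),
            fluorophore=_maybe(rng, p, rng.choice(_FLUOROPHORES)),
            excitation_wavelength=_maybe(rng, p, rng.choice((405, 488, 561, 640))),
            emission_wavelength=_maybe(rng, p, rng.choice((461, 519, 583, 668))),
        ))
    img.size_x = _maybe(rng, p, rng.choice((1024, 2048, 4096)))
    img.size_y = img.size_x
    img.size_z = _maybe(rng, p, rng.randrange(200, 4000))
    img.number_of_channels = _maybe(rng, p, len(img.channels))
    img.number_of_slices = img.size_z
    img.number_of_files = _maybe(rng, p, rng.randrange(1, 5000))
    img.number_of_timepoints = _maybe(rng, p, 1)
    if rng.random() < p:
        img.landmarks.append(LandmarkEntry(
            landmark_name=rng.choice(("bregma", "lambda", "anterior commissure")),
            landmark_x=rng.randrange(0, 2048),
            landmark_y=rng.randrange(0, 2048),
            landmark_z=rng.randrange(0, 2000),
        ))
    img.comments = _maybe(rng, p, _words(rng, 8).capitalize() + ".")

    mtype, mmodel = rng.choice(_MICROSCOPES)
    ins = rec.instrument
    ins.microscope_type = mtype
    ins.microscope_manufacturer_and_model = mmodel
    ins.objective_magnification = _maybe(rng, p, rng.choice((4, 10, 20, 25)))
    ins.objective_na = _maybe(rng, p, round(rng.uniform(0.3, 1.3), 2))
    ins.objective_immersion = _maybe(rng, p, rng.choice(_IMMERSIONS))
    ins.detector_type = _maybe(rng, p, rng.choice(_DETECTORS))
    ins.illumination_type = _maybe(rng, p, rng.choice(_ILLUMINATIONS))
    ins.illumination_wavelength = _maybe(rng, p, rng.choice((488, 561, 640)))
    ins.sample_temperature = _maybe(rng, p, round(rng.uniform(18.0, 25.0), 1))

    for _ in range(rng.randint(*config.n_publications)):
        rec.publications.append(PublicationEntry(
            related_identifier=f"10.{rng.randrange(1000, 9999)}/"
                               f"mms.{rng.randrange(10**6)}",
            related_identifier_type="DOI",
            relation_type=rng.choice(_RELATIONS),
            pmcid=_maybe(rng, 0.5, f"PMC{rng.randrange(10**7)}"),
            citation=_maybe(rng, 0.5, _words(rng, 8).capitalize() + "."),
        ))

    species, taxon = rng.choice(_SPECIES)
    s = rec.specimen
    s.species = species
    s.ncbi_taxonomy = taxon
    s.age = rng.choice((rng.randrange(1, 30), round(rng.uniform(0.5, 24.0), 1)))
    s.ageunit = rng.choice(("Days", "Months"))
    s.sex = rng.choice(("Male", "Female", "Unknown"))
    s.genotype = _maybe(rng, p, rng.choice(("wild type", "Thy1-GFP", "Cre;Ai14")))
    s.strain = _maybe(rng, p, "C57BL/6J" if species == "mouse" else None)
    s.organ = rng.choice(_ORGANS)
    s.organ_substructure = _maybe(rng, p, rng.choice(
        ("cortex", "hippocampus", "cerebellum", "olfactory bulb")))
    s.atlas = _maybe(rng, p, "Allen Mouse Brain Atlas" if species == "mouse" else None)
    s.sample_preparation = _maybe(rng, p, rng.choice(
        ("CLARITY cleared", "iDISCO cleared", "paraffin embedded")))
    return rec


# ---------------------------------------------------------------------------
# fault injection
# ---------------------------------------------------------------------------

# unconditionally required scalars safe to delete without colliding with the
# targets of any other recipe
_DELETABLE_REQUIRED = (
    ("Dataset.Title", "dataset", "title"),
    ("Dataset.Rights", "dataset", "rights"),
    ("Dataset.Abstract", "dataset", "abstract"),
    ("Image.xAxis", "image", "x_axis"),
    ("Image.yAxis", "image", "y_axis"),
    ("Image.zAxis", "image", "z_axis"),
    ("Instrument.MicroscopeType", "instrument", "microscope_type"),
    ("Instrument.MicroscopeManufacturerAndModel", "instrument",
     "microscope_manufacturer_and_model"),
    ("Specimen.Species", "specimen", "species"),
    ("Specimen.Ageunit", "specimen", "ageunit"),
)

# CARDINALITY empties the channel list, which would erase the targets of the
# channel-content recipes; the combination is rejected.
_INCOMPATIBLE_WITH_CARDINALITY = frozenset({"COLOR_FORMAT", "CHANNEL_MISMATCH"})


def _broken_check_digit(orcid: str) -> str:
    head, last = orcid[:-1], orcid[-1]
    replacement = "0" if last != "0" else "1"
    return head + replacement


def _inject_one(rec: MetadataRecord, code: str, at: str | None,
                rng: random.Random) -> FaultLabel:
    if code == "REQUIRED_MISSING":
        if at is not None:
            matches = [t for t in _DELETABLE_REQUIRED if t[0] == at]
            if not matches:
                raise ValueError(f"no REQUIRED_MISSING recipe for path {at!r}")
            path, block, attr = matches[0]
        else:
            path, block, attr = rng.choice(_DELETABLE_REQUIRED)
        setattr(getattr(rec, block), attr, None)
        return FaultLabel(path, code, f"deleted required field {path}")
    if code == "COND_FUNDERS":
        rec.funding_declared = True
        if rec.funders:
            rec.funders[0].award_title = None
            return FaultLabel("Funders[0].awardTitle", code,
                              "cleared a conditionally required funder field")
        return FaultLabel("Funders", code,
                          "declared government funding with no funder entries")
    if code == "COND_PERSONAL_ID":
        rng2 = rng
        entry = ContributorEntry(
            contributor_name=f"{rng2.choice(_LAST)}, {rng2.choice(_FIRST)}",
            creator=False,
            contributor_type="Researcher",
            name_type="Personal",
            affiliation=rng2.choice(_ORGS),
            affiliation_identifier=random_ror(rng2),
            affiliation_identifier_scheme="ROR",
        )
        rec.contributors.append(entry)
        i = len(rec.contributors) - 1
        return FaultLabel(f"Contributors[{i}].nameIdentifier", code,
                          "added a Personal contributor without identifiers")
    if code == "NO_CREATOR":
        if not rec.contributors:
            raise ValueError("NO_CREATOR recipe needs at least one contributor")
        for e in rec.contributors:
            e.creator = False
        return FaultLabel("Contributors", code, "cleared every creator flag")
    if code == "VOCAB_VIOLATION":
        rec.specimen.sex = "Hermaphrodite"
        return FaultLabel("Specimen.Sex", code,
                          "set Sex outside its controlled vocabulary")
    if code == "COLOR_FORMAT":
        if not rec.image.channels:
            raise ValueError("COLOR_FORMAT recipe needs at least one channel")
        rec.image.channels[0].display_color = (300, 0, 0)
        return FaultLabel("Image.Channels[0].displayColor", code,
                          "set an out-of-range display color component")
    if code == "STEP_NONPOSITIVE":
        rec.image.step_size_x = -1.0
        return FaultLabel("Image.stepSizeX", code, "set a negative step size")
    if code == "AGE_NEGATIVE":
        rec.specimen.age = -3
        return FaultLabel("Specimen.Age", code, "set a negative donor age")
    if code == "TAXON_SYNTAX":
        rec.specimen.ncbi_taxonomy = "10090x"
        return FaultLabel("Specimen.NCBITaxonomy", code,
                          "set a non-numeric taxonomy code")
    if code == "ID_SYNTAX":
        if not rec.contributors:
            raise ValueError("ID_SYNTAX recipe needs at least one contributor")
        good = random_orcid(rng)
        rec.contributors[0].name_identifier = _broken_check_digit(good)
        rec.contributors[0].name_identifier_scheme = "ORCID"
        return FaultLabel("Contributors[0].nameIdentifier", code,
                          "flipped the ORCID check digit")
    if code == "SPDX_HINT":
        rec.dataset.rights_identifier = "not an spdx code!!"
        return FaultLabel("Dataset.rightsIdentifier", code,
                          "set a rightsIdentifier with no SPDX token shape")
    if code == "SUGGESTED_VALUE_MISS":
        rec.dataset.general_modality = "zz-unlisted-modality"
        return FaultLabel("Dataset.generalModality", code,
                          "set a modality outside the suggested-value list")
    if code == "CARDINALITY":
        rec.image.channels = []
        return FaultLabel("Image.Channels", code, "removed every channel entry")
    if code == "CHANNEL_MISMATCH":
        if not rec.image.channels:
            raise ValueError("CHANNEL_MISMATCH recipe needs at least one channel")
        i = len(rec.image.channels) - 1
        rec.image.channels[i].number = None
        return FaultLabel(f"Image.Channels[{i}].Number", code,
                          "removed a channel's Number")
    if code == "VOCAB_CASE":
        rec.specimen.sex = "female"
        return FaultLabel("Specimen.Sex", code,
                          "lower-cased a vocabulary value")
    raise ValueError(f"no corruption recipe for code {code!r}")


def inject_errors(
    record: MetadataRecord, codes: list[str], seed: int = 0
) -> tuple[MetadataRecord, list[FaultLabel]]:
    """Return a corrupted copy of ``record`` plus one label per recipe.

    ``codes`` entries may carry an explicit target as ``CODE@path`` (only
    REQUIRED_MISSING recipes accept a target).  The original record is
    untouched.  Codes without a recipe, and the CARDINALITY /
    channel-content combination whose targets erase each other, raise
    ``ValueError``.
    """
    parsed = []
    for token in codes:
        code, _, at = token.partition("@")
        parsed.append((code, at or None))
    names = {c for c, _ in parsed}
    if "CARDINALITY" in names and names & _INCOMPATIBLE_WITH_CARDINALITY:
        raise ValueError(
            "CARDINALITY (empties the channel list) cannot be combined with "
            f"{sorted(names & _INCOMPATIBLE_WITH_CARDINALITY)}"
        )
    rng = random.Random(seed)
    out = record.copy()
    labels = [_inject_one(out, code, at, rng) for code, at in parsed]
    return out, labels


# codes drawn for random corpora: VOCAB_CASE and VOCAB_VIOLATION share a
# target, so only the error-level one is sampled; all 15 catalog codes keep
# dedicated recipes above.
_SAMPLEABLE = tuple(c for c in VALIDATION_CODES if c != "VOCAB_CASE")


def generate_corpus(
    n: int, config: GeneratorConfig, fault_rate: float = 0.0
) -> list[tuple[MetadataRecord, list[FaultLabel]]]:
    """Generate ``n`` records, each independently corrupted with
    probability ``fault_rate`` using 1-3 randomly chosen recipes.

    Fully reproducible from ``(n, config.seed, fault_rate)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= fault_rate <= 1.0:
        raise ValueError("fault_rate must be in [0, 1]")
    corpus = []
    for i in range(n):
        rec = generate_valid_record(config, index=i)
        labels: list[FaultLabel] = []
        rng = _rng_for(config.seed ^ 0x5EED, i)
        if rng.random() < fault_rate:
            k = rng.randint(1, 3)
            codes = rng.sample(_SAMPLEABLE, k)
            if "CARDINALITY" in codes:
                codes = [c for c in codes
                         if c not in _INCOMPATIBLE_WITH_CARDINALITY]
            rec, labels = inject_errors(rec, codes, seed=rng.randrange(2**31))
        corpus.append((rec, labels))
    return corpus
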