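"""End-to-end orchestration of the three-party protocol on in-memory tables.

This is the glue the CLI and the test harness share: mask each raw extract,
infer its structure, compile a per-site cleaning template, clean, encrypt
under a shared secret, and hand the encrypted extracts plus validation
tokens to the linkage engine.  Each helper corresponds to work done at one
site; nothing here weakens the confidentiality contract — the functions
exist so a simulation can drive all three parties inside one process.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import RecordTable
from .encryption import (EncryptionConfig, ValidationToken, encrypt_table,
                         make_validation)
from .linkage import (BlockingScheme, LinkageConfig, LinkageVariable,
                      Thresholds)
from .masking import MaskConfig, mask_table
from .preprocessing import (NicknameTable, PreprocessTemplate, apply_template,
                            compile_template, infer_structure)


@dataclass
class SiteArtifacts:
    """Everything one data-holding site produces for the linkage centre."""
    masked: RecordTable
    template: PreprocessTemplate
    cleaned: RecordTable
    encrypted: RecordTable
    validation: ValidationToken


def prepare_site(raw: RecordTable, crypt: EncryptionConfig,
                 nick: NicknameTable | None = None,
                 mask_cfg: MaskConfig | None = None) -> SiteArtifacts:
    """Run one site's full local pipeline: mask, template, clean, encrypt."""
    if nick is None:
        nick = NicknameTable.default()
    masked = mask_table(raw, mask_cfg)
    report = infer_structure(masked)
    template = compile_template(report)
    cleaned = apply_template(raw, template, nick)
    encrypted = encrypt_table(cleaned, crypt)
    return SiteArtifacts(masked=masked, template=template, cleaned=cleaned,
                         encrypted=encrypted,
                         validation=make_validation(crypt))


# ---------------------------------------------------------------------------
# Default linkage configuration for the generated extracts
# ---------------------------------------------------------------------------

def default_linkage_config(plain: bool = False) -> LinkageConfig:
    """m/u weights, thresholds and blocking for the synthetic schema.

    The m probabilities reflect the default error model (names survive
    cleaning unchanged on ~90 % of true pairs), the u probabilities the
    agreement chance on random pairs given the name-pool sizes and value
    distributions.  The upper threshold is set above the maximum score a
    pair can reach without any birth-date agreement (full names, sex,
    nationality and marital status minus the date disagreement weight comes
    to ~13.0), so namesakes alone can never be declared links; a typical
    true match scores >= 18.
    """
    variables = [
        LinkageVariable("SURNAME1", "name", m_prob=0.90, u_prob=0.005),
        LinkageVariable("SURNAME2", "name", m_prob=0.80, u_prob=0.01),
        LinkageVariable("FIRSTNAME1", "name", m_prob=0.90, u_prob=0.01),
        LinkageVariable("DOB", "date", m_prob=0.95, u_prob=0.0005),
        LinkageVariable("SEX", "plain", m_prob=0.98, u_prob=0.50),
        LinkageVariable("NATIONALITY", "plain", m_prob=0.95, u_prob=0.52),
        LinkageVariable("MARITAL", "plain", m_prob=0.90, u_prob=0.35),
    ]
    if plain:
        blocking = BlockingScheme([("DOB:year", "SEX"), ("DOB:daymonth",),
                                   ("SURNAME1",)])
    else:
        blocking = BlockingScheme([("DOB_year", "SEX"),
                                   ("DOB_enc:daymonth",), ("SURNAME1",)])
    return LinkageConfig(
        variables=variables,
        thresholds=Thresholds(upper=14.0, lower=2.0),
        blocking=blocking,
        transposition_pairs=[("FIRSTNAME1", "SURNAME1")],
    )
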