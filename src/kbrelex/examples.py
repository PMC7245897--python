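"""Hand-constructed miniature knowledge-store fixtures.

These are synthetic stand-ins shaped like real curated entries: an
Arabidopsis ethylene-response factor (ATERF1) whose name expansion yields
12 names and whose reaction neighbourhood yields 6 related entities, and a
Contactin-2 annotation record with the usual recommended / alternative /
gene name fields plus function text.  They exist so the name-expansion and
reaction-lookup walk-throughs can be exercised without any database access;
none of the reaction content is biologically curated.
"""

from __future__ import annotations

from .kb import KBRecord, KBStore, Reaction, ReactionModel


def aterf1_record() -> KBRecord:
    """A synthetic ATERF1 annotation record carrying 12 distinct names."""
    return KBRecord(
        accession="SYN-ERF1",
        recommended_name="ATERF1",
        alternative_names=[
            "Ethylene-responsive transcription factor 1",
            "Ethylene response factor 1",
            "Ethylene-responsive element-binding factor 1",
            "EREBP-2",
            "Ethylene-responsive element-binding protein 2",
        ],
        gene_names=["ERF1", "AT4G17500", "ERF-1"],
        short_names=["AtERF-1", "AtERF1a", "ERF1A"],
        function_text=(
            "Transcriptional activator binding the GCC-box of "
            "ethylene-responsive promoters; acts downstream of the "
            "ethylene signalling cascade."
        ),
        taxonomy="Arabidopsis thaliana",
    )


def aterf1_store() -> KBStore:
    """Store in which ATERF1 has exactly six reaction neighbours.

    Three curated reactions each match one of the record's names and
    contribute two new participants; a fourth reaction matches none of the
    names and must not contribute.
    """
    store = KBStore()
    store.add_record(aterf1_record())
    store.add_model(
        ReactionModel(
            "SYNBIOMD001",
            curated=True,
            reactions=[
                Reaction("rx1", ["ERF1", "Ethylene", "EIN3"]),
                Reaction("rx2", ["ATERF1", "EIN2", "CTR1"]),
                Reaction("rx3", ["AtERF-1", "ETR1", "PDF1.2"]),
                Reaction("rx4", ["ABI4", "ABA"]),
            ],
        )
    )
    return store


def contactin2_record() -> KBRecord:
    """A Contactin-2-shaped annotation record (names + function text)."""
    return KBRecord(
        accession="SYN-CNTN2",
        recommended_name="Contactin-2",
        alternative_names=[
            "Axonal glycoprotein TAG-1",
            "Axonin-1",
            "Transient axonal glycoprotein 1",
            "TAX-1",
        ],
        gene_names=["CNTN2"],
        short_names=[],
        function_text=(
            "Cell-adhesion glycoprotein of axonal membranes; helps organise "
            "voltage-gated potassium channels at juxtaparanodal regions of "
            "nodes of Ranvier together with CNTNAP2."
        ),
        taxonomy="Homo sapiens",
    )
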