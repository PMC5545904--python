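"""Hand-encoded worked example: celecoxib in the paired neuroinflammation
networks.

Celecoxib inhibits both of its principal targets, the cyclooxygenase PTGS2
and the kinase PDPK1. The mouse network encodes the normal-physiology
interactions reported from transgenic-mouse work (Pdpk1 activating Il4,
Ins, Akt1 and Gsk3b while restraining Ccr2, M1 macrophages and insulin
resistance; the Ptgs2 -> amyloid-beta -> Tnf/Nfkb1 -> Ptgs2 self-regulatory
inflammation loop). The human network encodes the perturbed-pathway
reasoning around the same drug: PDPK1 -> AKT1 -| TSC2 -> RHEB -> MTOR
-| autophagy -| amyloid-beta, the MTOR -> BACE1 arm, the AMPK (PRKAA1)
brake on MTOR, and the IL4 / INS arms whose suppression promotes
inflammation and insulin resistance.

Propagating the drug's -1 action through each network and comparing the
two species' net signs reproduces the qualitative cross-species
disagreement: beneficial amyloid-beta reduction in mouse versus increased
amyloid burden, reduced amyloid clearance and net inflammation in human.
"""

from __future__ import annotations

from .io import parse_bel_script, parse_term
from .model import CauseEffectModel
from .perturbation import DrugAction

MOUSE_CELECOXIB_BEL = """\
# species: mouse
SET Citation = "pdpk1-normal-physiology"
p(MGI:Pdpk1) increases act(p(MGI:Il4))
p(MGI:Pdpk1) increases p(MGI:Ins)
p(MGI:Pdpk1) decreases p(MGI:Ccr2)
p(MGI:Pdpk1) decreases cell(MESH:"M1 macrophage")
p(MGI:Pdpk1) decreases bp(GOBP:"insulin resistance")
SET Citation = "pdpk1-kinase-substrates"
p(MGI:Pdpk1) increases p(MGI:Akt1, pmod(Ph))
p(MGI:Pdpk1) increases p(MGI:Gsk3b, pmod(Ph))
SET Citation = "ptgs2-amyloid"
p(MGI:Ptgs2) increases a(CHEBI:"amyloid-beta")
SET Citation = "amyloid-inflammation-loop"
a(CHEBI:"amyloid-beta") increases p(MGI:Tnf)
a(CHEBI:"amyloid-beta") increases p(MGI:Nfkb1)
p(MGI:Nfkb1) increases p(MGI:Ptgs2)
p(MGI:Tnf) increases bp(GOBP:"inflammatory response")
SET Citation = "clearance-arms"
p(MGI:Ccr2) increases bp(GOBP:"amyloid-beta clearance")
cell(MESH:"M1 macrophage") increases bp(GOBP:"phagocytosis")
p(MGI:Gsk3b) increases p(MGI:Mapt, pmod(Ph))
"""

HUMAN_CELECOXIB_BEL = """\
# species: human
SET Citation = "akt-tsc-mtor-axis"
p(HGNC:PDPK1) increases p(HGNC:AKT1, pmod(Ph))
p(HGNC:AKT1) decreases p(HGNC:TSC2, pmod(Ph, Thr, 1462))
p(HGNC:TSC2) increases p(HGNC:RHEB)
p(HGNC:RHEB) increases p(HGNC:MTOR)
p(HGNC:MTOR) decreases bp(GOBP:"autophagy")
bp(GOBP:"autophagy") decreases a(CHEBI:"amyloid-beta")
bp(GOBP:"autophagy") increases bp(GOBP:"amyloid-beta clearance")
SET Citation = "mtor-bace1-arm"
p(HGNC:MTOR) increases p(HGNC:BACE1)
p(HGNC:BACE1) increases a(CHEBI:"amyloid-beta")
SET Citation = "il4-ins-arms"
p(HGNC:PDPK1) increases act(p(HGNC:IL4))
p(HGNC:IL4) decreases bp(GOBP:"inflammatory response")
p(HGNC:PDPK1) increases p(HGNC:INS)
p(HGNC:INS) decreases bp(GOBP:"insulin resistance")
SET Citation = "ampk-brake"
p(HGNC:PDPK1) increases p(HGNC:PRKAA1, pmod(Ph))
p(HGNC:PRKAA1) decreases p(HGNC:MTOR)
"""


def celecoxib_action() -> DrugAction:
    """Celecoxib inhibits PTGS2 (COX-2) and PDPK1 (PDK1): action sign -1."""
    return DrugAction(
        "celecoxib",
        (
            (parse_term("p(HGNC:PTGS2)"), -1),
            (parse_term("p(HGNC:PDPK1)"), -1),
        ),
    )


def celecoxib_case() -> tuple[CauseEffectModel, CauseEffectModel, DrugAction]:
    """(human model, mouse model, drug action) for the worked example."""
    human = parse_bel_script(HUMAN_CELECOXIB_BEL)
    mouse = parse_bel_script(MOUSE_CELECOXIB_BEL)
    return human, mouse, celecoxib_action()
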