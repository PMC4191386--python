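"""Bundled hammerhead design data.

The 54-nt target structure, the IUPAC design constraint string, the ten
selected hammerhead candidates HH1-HH10 with their selection criteria and
published kinetics/measure table, the 54-nt comparison sequence designed
by ensemble-defect minimization, and the 166-nt modular design.  These
are the published inputs of the design study and ship with the package so
that every analysis can be rerun without downloads.

``PLMVD_REFERENCE`` is a synthetic reconstruction: the wild-type viroid
reference sequence is recovered by inverting the design constraint string
(the codes B/D/H/V at the 38 unconstrained positions mean exactly "not
the wild-type nucleotide"; the conserved-site positions carry the
wild-type nucleotides; the cleavage site 8 is C).  It is faithful by
construction of the constraint string but is not an accession download.
"""

from __future__ import annotations

import math
from types import MappingProxyType

from .iofmt import DotBracket, IupacPattern, RnaSequence
from .measures import CONSERVED_SITE

#: 54-nt target secondary structure (hammerhead type III consensus).
TARGET_STRUCTURE = DotBracket(
    ".((((((.(((((...))))).......((((........))))...))))))."
)

#: IUPAC design constraint string (printed in blocks of 10).
DESIGN_PATTERN = IupacPattern(
    "HBVHBGUHVH VHDVBBHDBD BCUGAVGAGV DVBVHBBBVH BHBCGAAACV DBVB"
)

#: The ten selected hammerhead candidates.
HH_SEQUENCES = MappingProxyType({
    "HH1": "UUAAUGUAGAGCGAUUCGUUCCUGAAGAGCUAUAAUUUCUUAGCGAAACAUUAU",
    "HH2": "UUAUUGUAGCGCGAUUCGCGCCUGAAGAGAUGCGUUUUAACAUCGAAACAGUAU",
    "HH3": "CUAUUGUAGCGCGAUUCGCGCCUGAAGAGAUCUGUUUUAUGAUCGAAACAGUAU",
    "HH4": "UGGAUGUAGCGCGAUUCGCGCCUGAAGAGCGGUCAUCCAUCCGCGAAACAUUCU",
    "HH5": "CUCAGGUAGCGCGAUUCGCGCCUGAGGAGGGGUCUGGUAUCCCCGAAACCUGAU",
    "HH6": "UGGCGGUAGCGCGAUUCGCGCCUGAAGAGGGGUAACGCGUCCCCGAAACCGUCU",
    "HH7": "UCAAUGUCGCGCGAUUCGCGCCUGAAGAGAUGGAAUUUAACAUCGAAACAUUGU",
    "HH8": "UCAAUGUAGCGCGAUUCGCGCCUGAAGAGAUGGAAUUUAACAUCGAAACAUUGU",
    "HH9": "UUAAUGUCGCGCGAUUCGCGCCUGAAGAGAUCUGACUUCUGAUCGAAACAUUAU",
    "HH10": "UUAAGGUCGCGCGAUUCGCGCCUGACGAGCUAUAUUUUAUUAGCGAAACCUUAU",
})

#: Selection criteria label for each candidate.
HH_SELECTION = MappingProxyType({
    "HH1": "GC 30-39%, P(S0,s) >= 40%, smallest binary entropy discrepancy (site)",
    "HH2": "GC 40-49%, P(S0,s) >= 40%, smallest binary entropy discrepancy (site)",
    "HH3": "GC 40-49%, P(S0,s) >= 40%, second smallest binary entropy discrepancy (site)",
    "HH4": "GC 50-59%, P(S0,s) >= 40%, smallest binary entropy discrepancy (site)",
    "HH5": "GC 60-69%, P(S0,s) >= 40%, smallest binary entropy discrepancy (site)",
    "HH6": "GC 30-39%, P(S0,s) >= 40%, largest binary entropy discrepancy (site)",
    "HH7": "GUC at 6-8, smallest ensemble defect",
    "HH8": "smallest ensemble defect",
    "HH9": "P(S0,s) <= 20%, smallest binary entropy discrepancy (site)",
    "HH10": "smallest binary entropy discrepancy (site)",
})

#: Published cleavage kinetics and selection measures, one row per design:
#: K_obs (1/min), F_max, fit MSE, average full positional entropy (nats),
#: whole-molecule ensemble defect, conserved-site EBPD discrepancy.
KINETICS_TABLE = MappingProxyType({
    "HH1": dict(k_obs=0.037, f_max=0.79, mse=0.0029,
                pos_entropy=0.270882, ensemble_defect=4.167687, ebpd_disc_site=0.0501207),
    "HH2": dict(k_obs=0.0057, f_max=0.74, mse=0.003,
                pos_entropy=0.287235, ensemble_defect=4.552053, ebpd_disc_site=0.0386253),
    "HH3": dict(k_obs=0.0027, f_max=0.65, mse=0.0039,
                pos_entropy=0.259577, ensemble_defect=4.121914, ebpd_disc_site=0.0410984),
    "HH4": dict(k_obs=0.0127, f_max=0.55, mse=0.0048,
                pos_entropy=0.403846, ensemble_defect=6.755976, ebpd_disc_site=0.0354213),
    "HH5": dict(k_obs=0.0085, f_max=0.52, mse=0.0066,
                pos_entropy=0.382235, ensemble_defect=6.240083, ebpd_disc_site=0.033132),
    "HH6": dict(k_obs=0.102, f_max=0.73, mse=0.0047,
                pos_entropy=0.414872, ensemble_defect=8.138131, ebpd_disc_site=0.059864),
    "HH7": dict(k_obs=0.25, f_max=0.74, mse=0.0107,
                pos_entropy=0.119159, ensemble_defect=2.383671, ebpd_disc_site=0.0406728),
    "HH8": dict(k_obs=0.02, f_max=0.68, mse=0.0124,
                pos_entropy=0.078518, ensemble_defect=1.45179, ebpd_disc_site=0.0662421),
    "HH9": dict(k_obs=0.025, f_max=0.76, mse=0.0015,
                pos_entropy=0.247886, ensemble_defect=4.525597, ebpd_disc_site=0.0328018),
    "HH10": dict(k_obs=0.14, f_max=0.77, mse=0.01,
                 pos_entropy=0.286425, ensemble_defect=4.975979, ebpd_disc_site=0.0269354),
})

#: 54-nt comparison sequence designed by ensemble-defect minimization
#: (first sequence returned by the NUPACK web server for the same target).
NUPACK_SEQUENCE = RnaSequence(
    "NUPACK-1",
    "CGCCGGUAGC CUGACCCAGG CCUGAAGAGC UCUACCCCCC GAGCGAAACC GGCU".replace(" ", ""),
)

#: 166-nt modular design: hammerhead embedded in a purine-riboswitch-like
#: scaffold, self-cleaving at the GUC site 114-116.
MODULAR_166 = RnaSequence(
    "modular-166",
    (
        "GCCGC GUAUA AGGGC UGCGA UAAGG GCAGU CCGUU UCUAC GGGCG GCCGU "
        "AAACC GCCCA CUACG CGGCG UGGUU AAGCC GGAAA GGAGA CCGGC AGGAG "
        "GGUAA UGGGC CGCGU CGCGG CGCGG GAGCG CGCCG CCUGA UGAGU CCGUG "
        "AGGAC GAAAC GCGGCC"
    ).replace(" ", ""),
)

#: Wild-type nucleotides at the conserved site (positions with >96%
#: identity in the family seed alignment, plus cleavage site C8).
CONSERVED_NUCLEOTIDES = MappingProxyType({
    6: "G", 7: "U", 22: "C", 23: "U", 24: "G", 25: "A",
    27: "G", 28: "A", 29: "G",
    44: "C", 45: "G", 46: "A", 47: "A", 48: "A", 49: "C",
})

_NOT_CODE_INVERSE = {"B": "A", "D": "C", "H": "G", "V": "U"}


def _reconstruct_reference() -> RnaSequence:
    residues = []
    for pos, code in enumerate(DESIGN_PATTERN.codes, start=1):
        if pos in CONSERVED_NUCLEOTIDES:
            residues.append(CONSERVED_NUCLEOTIDES[pos])
        elif pos == 8:
            residues.append("C")  # cleavage site, excluded from the >96% set
        else:
            residues.append(_NOT_CODE_INVERSE[code])
    return RnaSequence("PLMVd-reconstructed", "".join(residues))


#: Synthetic reconstruction of the wild-type reference (see module docstring).
PLMVD_REFERENCE = _reconstruct_reference()

#: Frozen outcome of calibrating the ensemble model against the published
#: measure table over all ten designs (see
#: :func:`ribodesign.measures.calibrate_table_reproduction`): dangle mode 2
#: with entropies in nats minimizes the worst-case relative error; the
#: recorded maxima bound the engine-version drift of the reproduction.
TABLE2_CALIBRATION = MappingProxyType({
    "parameter_set": "turner1999",
    "dangles": 2,
    "entropy_log_base": math.e,
    "max_rel_err_pos_entropy": 0.747,
    "max_rel_err_ensemble_defect": 0.867,
})

__all__ = [
    "TARGET_STRUCTURE",
    "DESIGN_PATTERN",
    "HH_SEQUENCES",
    "HH_SELECTION",
    "KINETICS_TABLE",
    "NUPACK_SEQUENCE",
    "MODULAR_166",
    "CONSERVED_NUCLEOTIDES",
    "CONSERVED_SITE",
    "PLMVD_REFERENCE",
    "TABLE2_CALIBRATION",
]
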