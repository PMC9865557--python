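import numpy as np
import pytest

from ilscale import read_topology

TOPOLOGY_TEXT = """\
; toy quinuclidinium-like ionic-liquid topology (fixture)
[ defaults ]
; nbfunc comb-rule gen-pairs fudgeLJ fudgeQQ
1 2 yes 0.5 0.8333

[ atomtypes ]
; name  at.num  mass     charge  ptype  sigma    epsilon
NQ      7       14.007   0.0     A      0.325    0.711
CQ      6       12.011   0.0     A      0.340    0.457
HQ      1       1.008    0.0     A      0.247    0.0657
NTN     7       14.007   0.0     A      0.325    0.711
FTN     9       18.998   0.0     A      0.312    0.255
CS      6       12.011   0.0     A      0.350    0.276
HS      1       1.008    0.0     A      0.250    0.0628

[ moleculetype ]
; name nrexcl
QUIN 3

[ atoms ]
;  nr type resnr residue atom cgnr charge   mass
   1  NQ   1     QUIN    N1   1    0.40     14.007
   2  CQ   1     QUIN    C1   1    0.30     12.011
   3  HQ   1     QUIN    H1   1    0.10     1.008
   4  HQ   1     QUIN    H2   1    0.10     1.008
   5  HQ   1     QUIN    H3   1    0.10     1.008

[ bonds ]
; this block is opaque passthrough and must survive byte-identically
   1   2   1   0.1529   224262.4
   2   3   1   0.1090   284512.0

[ moleculetype ]
NTF 3

[ atoms ]
   1  NTN  1     NTF     N1   1   -0.60     14.007
   2  FTN  1     NTF     F1   1   -0.20     18.998
   3  FTN  1     NTF     F2   1   -0.20     18.998

[ moleculetype ]
SOL 3

[ atoms ]
   1  CS   1     SOL     C1   1   -0.40     12.011
   2  HS   1     SOL     H1   1    0.20     1.008
   3  HS   1     SOL     H2   1    0.20     1.008

[ system ]
toy IL box

[ molecules ]
QUIN 170
NTF  170
SOL  1
"""


@pytest.fixture
def topology_text():
    return TOPOLOGY_TEXT


@pytest.fixture
def topology():
    return read_topology(TOPOLOGY_TEXT)


def assert_topology_equal(a, b, rtol=1e-12):
    """Structural equality of two topologies with numeric tolerance."""
    assert list(a.atom_types) == list(b.atom_types)
    for name in a.atom_types:
        ta, tb = a.atom_types[name], b.atom_types[name]
        assert ta.ptype == tb.ptype
        np.testing.assert_allclose(
            [ta.sigma, ta.epsilon, ta.mass, ta.charge],
            [tb.sigma, tb.epsilon, tb.mass, tb.charge],
            rtol=rtol,
        )
    assert [m.name for m in a.molecules] == [m.name for m in b.molecules]
    for ma, mb in zip(a.molecules, b.molecules):
        assert ma.nrexcl == mb.nrexcl
        assert ma.role == mb.role
        assert ma.passthrough == mb.passthrough
        assert len(ma.atoms) == len(mb.atoms)
        for xa, xb in zip(ma.atoms, mb.atoms):
            assert (xa.index, xa.type_name, xa.residue, xa.name) == (
                xb.index, xb.type_name, xb.residue, xb.name)
            np.testing.assert_allclose(
                [xa.charge, xa.mass], [xb.charge, xb.mass], rtol=rtol)
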