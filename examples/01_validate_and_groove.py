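"""Curation filters and groove selection on a synthetic p-HLA complex.

Builds the packaged mini-groove fixture with a bound 9-mer, runs the
benchmark curation filters, and selects the 37 solvent-accessible
binding-groove residues by their HLA-A*02:01 numbers.
"""

from anchordock import default_groove, select_groove, validate_complex
from anchordock.fixtures import FixtureSpec, generate_complex

complex_ = generate_complex(FixtureSpec())
ok, reasons = validate_complex(complex_)
print(f"complex {complex_.id}: {'ACCEPT' if ok else 'REJECT'} {reasons}")

groove = select_groove(complex_, default_groove())
print(f"groove selection: {len(groove)} residues, "
      f"first {groove[0].name}{groove[0].number}, "
      f"last {groove[-1].name}{groove[-1].number}")

# a gapped peptide is rejected by the same filters the benchmark set used
gapped = complex_.copy()
del gapped.chains["C"][4]
ok, reasons = validate_complex(gapped)
print(f"gapped copy: {'ACCEPT' if ok else 'REJECT'} ({reasons[0]})")

# ACCEPT means the peptide is a complete, ungapped nonamer of standard
# residues; the 37-residue selection is the scoring/flexibility region.
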