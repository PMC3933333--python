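"""Contrasts computable from the packaged clinical table alone.

The 16-case table (8 autism, 8 control; 5 males and 3 females each) ships
with the package; one control male has no recorded brain weight.  The
female cases have ~13.5% lower fresh brain weight than the males, and the
male cases span a wider age range.
"""

from pcstereo.analysis import table1_report

report = table1_report()
bw = report["brain_weight"]
age = report["age"]
print(f"cases: {report['n_cases']} "
      f"(with brain weight: {report['n_with_brain_weight']})")
print(f"brain weight, F vs M: {bw['percent_difference']:.1f}% lower in "
      f"females (t={bw['t']:.3f}, df={bw['df']:.0f}, p={bw['p']:.3f}, "
      f"{bw['flavor']})")
print(f"age, M vs F:          t={age['t']:.2f}, df={age['df']:.1f}, "
      f"p={age['p']:.3f} ({age['flavor']})")
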