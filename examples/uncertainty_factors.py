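"""The analytic map from interindividual CV to uncertainty factors.

For a lognormal PK parameter the UF at percentile p is
exp(z_p * sqrt(ln(1 + CV^2))): the fold-difference between the p-th
percentile individual and the median individual.  The table below spans the
CV range seen across UGT probe substrates (about 23% to 67%).
"""

from ugtvar.uf import DEFAULT_TK_UF, sigma_from_cv, uf_from_cv

print(f"{'CV%':>4} {'sigma':>6} {'UF95':>6} {'UF97.5':>7}")
for cv_pct in (23, 28, 33, 40, 44, 50, 59, 67):
    cv = cv_pct / 100.0
    print(
        f"{cv_pct:>4} {sigma_from_cv(cv):6.3f} "
        f"{uf_from_cv(cv, 95.0):6.2f} {uf_from_cv(cv, 97.5):7.2f}"
    )
print(f"\ndefault toxicokinetic UF for comparison: {DEFAULT_TK_UF}")
# A UF97.5 above 3.16 means more than 2.5% of healthy adults differ from
# the median by more than the default toxicokinetic factor allows.
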