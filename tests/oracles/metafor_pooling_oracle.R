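# Independent oracle for the pooling cross-check constants frozen in
# tests/test_pooling.py (METAFOR_MH / METAFOR_DL). Recomputes the
# Mantel-Haenszel (RBG variance) and DerSimonian-Laird pools of the
# rs8051542 allele-model tables with R metafor. Not run by the test suite;
# rerun manually with: Rscript tests/oracles/metafor_pooling_oracle.R
library(metafor)
d <- read.delim("src/snpmeta/data/rs8051542.tsv", check.names = FALSE)
ai <- 2 * d$cases_hom_risk + d$cases_het      # risk (T) alleles, cases
bi <- 2 * d$cases_hom_ref + d$cases_het       # reference (C) alleles, cases
ci <- 2 * d$controls_hom_risk + d$controls_het
di <- 2 * d$controls_hom_ref + d$controls_het
mh <- rma.mh(ai = ai, bi = bi, ci = ci, di = di, measure = "OR", correct = FALSE)
cat(sprintf("MH: or=%.10f se=%.10f\n", exp(coef(mh)), mh$se))
dl <- rma(ai = ai, bi = bi, ci = ci, di = di, measure = "OR", method = "DL")
cat(sprintf("DL: or=%.10f se=%.10f tau2=%.10f Q=%.10f Qp=%.10f I2=%.10f\n",
            exp(coef(dl)), dl$se, dl$tau2, dl$QE, dl$QEp, dl$I2))
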