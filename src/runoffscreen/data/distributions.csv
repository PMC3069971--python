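# Lognormal distribution parameters for pesticide properties, maximum-likelihood
# estimates over registration-study medians for 172 pesticides.
# mu/sigma are the mean and sd of the natural logarithm; mean/sd are the
# corresponding arithmetic moments of the variable itself as published.
# AERO: aerobic soil metabolism half-life (days); KOC: organic-carbon-normalized
# sorption coefficient (L/kg-OC).
variable,mu,sigma,mean,sd
AERO,3.44,1.99,226.01,1613.14
KOC,6.51,2.52,1.61e4,3.82e5
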