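# Default "drug abuse and dependence" preferred-term set.
# MedDRA SMQ contents are licensed and not redistributable, so this is a
# documented default covering the common abuse / dependence / misuse /
# overdose preferred terms; replace with a licensed term file if available.
Drug abuse
Drug abuser
Drug dependence
Drug withdrawal syndrome
Drug withdrawal convulsions
Intentional product misuse
Substance abuse
Substance use disorder
Overdose
Intentional overdose
Accidental overdose
Toxicity to various agents
Drug diversion
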