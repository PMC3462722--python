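>osa-miR168a rice, monocot variant
UCGCUUGGUGCAGAUCGGGAC
>zma-miR168a corn, monocot variant
UCGCUUGGUGCAGAUCGGGAC
>zma-miR168b corn, monocot variant
UCGCUUGGUGCAGAUCGGGAC
>sbi-miR168 sorghum, monocot variant
UCGCUUGGUGCAGAUCGGGAC
>ath-miR168a Arabidopsis, dicot variant
UCGCUUGGUGCAGGUCGGGAA
>ath-miR168b Arabidopsis, dicot variant
UCGCUUGGUGCAGGUCGGGAA
>gma-miR168 soybean, dicot variant
UCGCUUGGUGCAGGUCGGGAA
>bna-miR168 oilseed rape, dicot variant
UCGCUUGGUGCAGGUCGGGAA
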