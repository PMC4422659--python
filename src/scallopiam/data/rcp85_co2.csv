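# RCP8.5 global mean atmospheric CO2 concentration (ppm), 5-year anchors
# from the harmonized RCP concentration database (Meinshausen et al. 2011);
# annual values are obtained by linear interpolation.
year,co2_ppm
2000,368.9
2005,378.8
2010,389.1
2015,401.5
2020,415.8
2025,431.4
2030,448.8
2035,468.2
2040,489.4
2045,513.5
2050,540.5
2055,571.3
2060,604.0
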