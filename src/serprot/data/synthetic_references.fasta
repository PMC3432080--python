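>trypsin synthetic trypsin-like zymogen reference scaffold
VNPRIVGGHHQGERANDEEWVEDYRITWANDHLRVRPASKNDWGSAAHCYHTSGIPIITA
EGSQCMWAFIINVNFAHPNTEDTPPSMTDGEPNDIVWFKWHWTENGRKTEPRGIYAPVLF
NVYLWIVEHQLSFGIIALVVSMPQIRLAKNPGEYHIQQACEGWSRDQTHQCELWMGGFHP
QIGSWIIEDTQGGDSGGPWLLQEDNCAFRHEEFQFTIMNSVRARACYAMEYPNA
>chymotrypsin synthetic chymotrypsin-like zymogen reference scaffold
VNPRIVGGHPQGETGKDEEWVEDYAITQSFWHARGRPRMYRPWSSAAHCYHYSGQVIIAL
NGSKCMWAFIHKINQAHPNTWNSMPSMHWNEPNDIKWFQWHWTENHYKTEVSGNYAPDWF
NVQLWIFEHSLSFGIIAADVAMPQVDLALNPMEYNIWYECHGPSHYQTHQCEYWMMSFPP
QIGDGPIESTQGGDSGGPWLPHVDNCQVDMEKFQMTIMLSLRARACYAMEYFNA
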