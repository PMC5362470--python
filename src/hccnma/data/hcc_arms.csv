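article_id,arm_id,treatment,n_enrolled,rows
peng_2013,peng_2013:TACE+RFA,TACE+RFA,94,main
peng_2013,peng_2013:RFA,RFA,95,main
muhammad_2013,muhammad_2013:TACE+SOR,TACE+SOR,13,main
muhammad_2013,muhammad_2013:TACE,TACE,30,main
bai_2013,bai_2013:TACE+SOR,TACE+SOR,82,main
bai_2013,bai_2013:TACE,TACE,164,main
nicolini_2013,nicolini_2013:DEB-TACE,DEB-TACE,22,main
nicolini_2013,nicolini_2013:TACE,TACE,16,main
moreno_luna_2013,moreno_luna_2013:TARE-90Y,TARE-90Y,61,main
moreno_luna_2013,moreno_luna_2013:TACE,TACE,55,main
qu_2012,qu_2012:TACE+SOR,TACE+SOR,45,main
qu_2012,qu_2012:TACE,TACE,45,main
song_2012,song_2012:DEB-TACE,DEB-TACE,60,main
song_2012,song_2012:TACE,TACE,69,main
recchia_2012,recchia_2012:DEB-TACE,DEB-TACE,35,main
recchia_2012,recchia_2012:TACE,TACE,70,main
peng_2011,peng_2011:TACE+RFA,TACE+RFA,69,main
peng_2011,peng_2011:RFA,RFA,70,main
kudo_2011,kudo_2011:TACE+SOR,TACE+SOR,229,main
kudo_2011,kudo_2011:TACE,TACE,229,main
song_2011,song_2011:DEB-TACE,DEB-TACE,20,main
song_2011,song_2011:TACE,TACE,20,main
salem_2011,salem_2011:TARE-90Y,TARE-90Y,123,main
salem_2011,salem_2011:TACE,TACE,122,main
wiggerman_2011,wiggerman_2011:DEB-TACE,DEB-TACE,22,main
wiggerman_2011,wiggerman_2011:TACE,TACE,22,main
sacco_2011,sacco_2011:DEB-TACE,DEB-TACE,33,main
sacco_2011,sacco_2011:TACE,TACE,34,main
malagari_2011,malagari_2011:DEB-TACE,DEB-TACE,41,main
malagari_2011,malagari_2011:TACE,TACE,43,main
kim_2010,kim_2010:TACE+RFA,TACE+RFA,83,main
kim_2010,kim_2010:RFA,RFA,231,main
morimoto_2010,morimoto_2010:TACE+RFA,TACE+RFA,19,main
morimoto_2010,morimoto_2010:RFA,RFA,18,main
li_2010,li_2010:TACE+HIFU,TACE+HIFU,44,main
li_2010,li_2010:TACE,TACE,45,main
tan_2010,tan_2010:TACE+SOR,TACE+SOR,10,main
tan_2010,tan_2010:TACE,TACE,10,main
kooby_2010,kooby_2010:TARE-90Y,TARE-90Y,27,main
kooby_2010,kooby_2010:TACE,TACE,44,main
carr_2010,carr_2010:TARE-90Y,TARE-90Y,99,main
carr_2010,carr_2010:TACE,TACE,691,main
ferrer_puchol_2010,ferrer_puchol_2010:DEB-TACE,DEB-TACE,47,main
ferrer_puchol_2010,ferrer_puchol_2010:TACE,TACE,25,main
dhanasekaran_2010,dhanasekaran_2010:DEB-TACE,DEB-TACE,45,main
dhanasekaran_2010,dhanasekaran_2010:TACE,TACE,26,main
shibata_2009,shibata_2009:TACE+RFA,TACE+RFA,46,main
shibata_2009,shibata_2009:TACE,TACE,43,main
yang_2009,yang_2009:TACE+RFA,TACE+RFA,31,a|b
yang_2009,yang_2009:RFA,RFA,37,a|c
yang_2009,yang_2009:TACE,TACE,35,b|c
cheng_2008,cheng_2008:TACE+RFA,TACE+RFA,96,a|b
cheng_2008,cheng_2008:RFA,RFA,100,a|c
cheng_2008,cheng_2008:TACE,TACE,95,b|c
brunello_2008,brunello_2008:RFA,RFA,70,main
brunello_2008,brunello_2008:PEI,PEI,69,main
wu_2005,wu_2005:TACE+HIFU,TACE+HIFU,24,main
wu_2005,wu_2005:TACE,TACE,26,main
becker_2005,becker_2005:TACE+PEI,TACE+PEI,27,main
becker_2005,becker_2005:TACE,TACE,25,main
shiina_2005,shiina_2005:RFA,RFA,118,main
shiina_2005,shiina_2005:PEI,PEI,114,main
lin_2005,lin_2005:PAI,PAI,63,main
lin_2005,lin_2005:PEI,PEI,62,main
shim_2005,shim_2005:TACE+RT,TACE+RT,38,main
shim_2005,shim_2005:TACE,TACE,35,main
lin_2004,lin_2004:a:RFA,RFA,50,a
lin_2004,lin_2004:a:PEI,PEI,46,a
lin_2004,lin_2004:b:RFA,RFA,50,b
lin_2004,lin_2004:b:PEI,PEI,50,b
zeng_2004,zeng_2004:TACE+EBRT,TACE+EBRT,54,main
zeng_2004,zeng_2004:TACE,TACE,149,main
lencioni_2003,lencioni_2003:RFA,RFA,52,main
lencioni_2003,lencioni_2003:PEI,PEI,50,main
guo_2003,guo_2003:TACE+RT,TACE+RT,76,main
guo_2003,guo_2003:TACE,TACE,89,main
kamada_2002,kamada_2002:TACE+PEI,TACE+PEI,32,main
kamada_2002,kamada_2002:TACE,TACE,37,main
koda_2001,koda_2001:TACE+PEI,TACE+PEI,26,main
koda_2001,koda_2001:PEI,PEI,26,main
cheng_2001,cheng_2001:TACE+RT,TACE+RT,17,a|b
cheng_2001,cheng_2001:RT,RT,9,b|c
cheng_2001,cheng_2001:TACE,TACE,16,a|c
allgaier_1998,allgaier_1998:TACE+PEI,TACE+PEI,39,a|b
allgaier_1998,allgaier_1998:TACE,TACE,33,b|c
allgaier_1998,allgaier_1998:PEI,PEI,15,a|c
bartolozzi_1995,bartolozzi_1995:TACE+PEI,TACE+PEI,26,main
bartolozzi_1995,bartolozzi_1995:TACE,TACE,27,main
kato_1994,kato_1994:TACE+PEI,TACE+PEI,24,main
kato_1994,kato_1994:TACE,TACE,22,main
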